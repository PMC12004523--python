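"""The virtual-screening triage funnel.

A purchasable library is reduced to a diverse, novel shortlist through an
ordered cascade of filters:

1. **ro5** -- rule-of-five drug-likeness, implemented in its original form
   (at most one violation of MW <= 500, logP <= 5, HBD <= 5, HBA <= 10).
2. **CYP motif** -- require an aromatic imidazole, 1,2,3-/1,2,4-triazole, or
   pyridine ring, the canonical heme-iron-coordinating substructures of
   CYP inhibitors.
3. **ensemble gate** -- keep a compound if any of the four classifier
   probabilities ranks it in the top N for that model AND its maximum
   probability exceeds p_min (strictly).
4. **novelty** -- drop compounds with Tanimoto similarity >= 0.7 to any
   known active (strict "below 0.7" survives).
5. **liability** -- PAINS alerts plus structural liabilities: net positive
   charge, long unbranched alkane chains (>= 7 consecutive sp3 carbons),
   bromine/iodine, nitro groups, basic aliphatic amines, and more than 8
   rotatable bonds.  The basic-amine pattern deliberately spares amides,
   anilines and aromatic azole nitrogens so the mandatory CYP motif is
   never self-contradictory.
6. **diversity** -- Butina clustering at centroid similarity 0.6; one
   representative per cluster (highest ensemble probability, ties to the
   lowest compound id).

Everything downstream (docking, visual inspection) is manual; the funnel
ends with a ranked candidate sheet and a full per-stage audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem.FilterCatalog import FilterCatalog, FilterCatalogParams

from .chemspace import ecfp4, tanimoto_matrix
from .modeling import butina_cluster
from .records import CompoundRecord

# aromatic five-membered azoles and pyridine-type six-membered N-heterocycles
CYP_MOTIF_SMARTS = {
    "imidazole": "c1cncn1",
    "triazole_123": "c1cnnn1",
    "triazole_124": "c1ncnn1",
    "pyridine": "c1ccncc1",
}

LIABILITY_SMARTS = {
    # >= 7 consecutive unbranched sp3 carbons (terminal atoms may be CH3)
    "long_alkane": "[CX4;H2,H3][CX4H2][CX4H2][CX4H2][CX4H2][CX4H2][CX4;H2,H3]",
    "heavy_halogen": "[Br,I]",
    "nitro": "[$([NX3](=O)=O),$([NX3+](=O)[O-])]",
    # aliphatic amine N, neutral, not amide/sulfonamide, not aniline,
    # not double-bonded (imine/amidine) -- aromatic azole n is excluded
    # because the pattern only matches aliphatic (uppercase) nitrogen
    "basic_amine": "[NX3;+0;!$(N-C=[O,S,N]);!$(N-S(=O));!$(N-a);!$(N=*)]",
}


@dataclass
class FunnelConfig:
    """Thresholds and patterns of the triage cascade."""

    top_n: int = 10000
    p_min: float = 0.7
    novelty_max_sim: float = 0.7
    diversity_sim: float = 0.6
    rotatable_bond_max: int = 8
    motif_smarts: dict = field(default_factory=lambda: dict(CYP_MOTIF_SMARTS))
    liability_smarts: dict = field(default_factory=lambda: dict(LIABILITY_SMARTS))

    def __post_init__(self):
        if not (0 <= self.p_min <= 1 and 0 <= self.novelty_max_sim <= 1 and 0 <= self.diversity_sim <= 1):
            raise ValueError("similarity/probability thresholds must lie in [0, 1]")
        if self.top_n < 1 or self.rotatable_bond_max < 0:
            raise ValueError("invalid count threshold")
        for name, smarts in {**self.motif_smarts, **self.liability_smarts}.items():
            if Chem.MolFromSmarts(smarts) is None:
                raise ValueError(f"unparseable SMARTS for {name!r}")


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_out: int
    survivors: list


@dataclass
class FunnelReport:
    """Ordered stages with nested survivor sets and first-failure reasons."""

    stages: List[FunnelStage] = field(default_factory=list)
    failure_reasons: Dict[str, str] = field(default_factory=dict)
    shortlist: list = field(default_factory=list)  # (id, max_proba) ranked
    max_proba: Dict[str, float] = field(default_factory=dict)  # gate-scored ids

    def add(self, name: str, survivors_in: list, survivors_out: list, reasons: dict):
        self.stages.append(
            FunnelStage(name, len(survivors_in), len(survivors_out), list(survivors_out))
        )
        for cid, why in reasons.items():
            self.failure_reasons.setdefault(cid, f"{name}: {why}")

    def counts(self) -> list:
        return [(s.name, s.n_in, s.n_out) for s in self.stages]

    def validate(self) -> None:
        prev = None
        for s in self.stages:
            if prev is not None:
                if s.n_in != len(prev.survivors) or not set(s.survivors) <= set(prev.survivors):
                    raise ValueError(f"stage {s.name!r} is not nested in its predecessor")
            if s.n_out > s.n_in:
                raise ValueError(f"stage {s.name!r} count increased")
            prev = s

    def to_dict(self) -> dict:
        return {
            "stages": [
                {"name": s.name, "n_in": s.n_in, "n_out": s.n_out, "survivors": s.survivors}
                for s in self.stages
            ],
            "failure_reasons": self.failure_reasons,
            "shortlist": [{"compound_id": c, "max_proba": p} for c, p in self.shortlist],
            "max_proba": self.max_proba,
        }


# ---------------------------------------------------------------------------
# single-molecule predicates
# ---------------------------------------------------------------------------

def ro5_filter(mol: Chem.Mol) -> bool:
    """Rule of five with the classic one-violation allowance."""
    violations = 0
    violations += Descriptors.MolWt(mol) > 500
    violations += Crippen.MolLogP(mol) > 5
    violations += Lipinski.NumHDonors(mol) > 5
    violations += Lipinski.NumHAcceptors(mol) > 10
    return violations <= 1


def cyp_motif_filter(mol: Chem.Mol, motif_smarts: Optional[dict] = None) -> bool:
    """True iff the molecule bears an aromatic azole or pyridine ring."""
    patterns = motif_smarts if motif_smarts is not None else CYP_MOTIF_SMARTS
    return any(mol.HasSubstructMatch(Chem.MolFromSmarts(s)) for s in patterns.values())


_pains_cache: dict = {}


def _pains_catalog() -> FilterCatalog:
    if "cat" not in _pains_cache:
        params = FilterCatalogParams()
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_A)
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_B)
        params.AddCatalog(FilterCatalogParams.FilterCatalogs.PAINS_C)
        _pains_cache["cat"] = FilterCatalog(params)
    return _pains_cache["cat"]


def liability_filter(mol: Chem.Mol, config: Optional[FunnelConfig] = None) -> tuple:
    """(passes, reasons) against PAINS and structural-liability rules."""
    cfg = config or FunnelConfig()
    reasons = []
    if _pains_catalog().HasMatch(mol):
        reasons.append("pains")
    if Chem.GetFormalCharge(mol) > 0:
        reasons.append("positive-charge")
    for name, smarts in cfg.liability_smarts.items():
        if mol.HasSubstructMatch(Chem.MolFromSmarts(smarts)):
            reasons.append(name)
    if rdMolDescriptors.CalcNumRotatableBonds(mol) > cfg.rotatable_bond_max:
        reasons.append("rotatable-bonds")
    return (len(reasons) == 0), reasons


# ---------------------------------------------------------------------------
# set-level stages
# ---------------------------------------------------------------------------

def ensemble_gate(
    compound_ids: Sequence[str],
    proba: np.ndarray,
    top_n: int = 10000,
    p_min: float = 0.7,
) -> list:
    """Rank/probability gate over an (n_compounds x n_models) matrix.

    A compound survives iff some model ranks it within that model's top_n
    (descending probability, ties broken by compound id) and its maximum
    probability across models strictly exceeds p_min.
    """
    proba = np.asarray(proba, dtype=np.float64)
    n, m = proba.shape
    ids = np.asarray(compound_ids)
    in_top = np.zeros(n, dtype=bool)
    id_order = np.argsort(ids, kind="stable")
    for j in range(m):
        # sort by descending probability; ties resolved by ascending id
        order = id_order[np.argsort(-proba[id_order, j], kind="stable")]
        in_top[order[:top_n]] = True
    keep = in_top & (proba.max(axis=1) > p_min)
    return [str(ids[i]) for i in range(n) if keep[i]]


def novelty_filter(
    candidate_fps: np.ndarray,
    candidate_ids: Sequence[str],
    known_active_fps: np.ndarray,
    max_sim: float = 0.7,
) -> tuple:
    """Keep candidates strictly below ``max_sim`` to every known active.

    Returns (survivor ids, max similarity per candidate)."""
    if len(known_active_fps) == 0:
        return list(candidate_ids), np.zeros(len(candidate_ids))
    nn = tanimoto_matrix(candidate_fps, known_active_fps).max(axis=1)
    keep = nn < max_sim
    return [cid for cid, k in zip(candidate_ids, keep) if k], nn


def diversity_select(
    survivor_ids: Sequence[str],
    survivor_fps: np.ndarray,
    max_proba: Sequence[float],
    diversity_sim: float = 0.6,
) -> tuple:
    """Butina-cluster survivors and keep one representative per cluster.

    The representative is the member with the highest ensemble probability;
    ties go to the lowest compound id.  Returns (representative ids,
    cluster id per survivor)."""
    if len(survivor_ids) == 0:
        return [], np.zeros(0, dtype=np.int64)
    clusters = butina_cluster(survivor_fps, similarity_floor=diversity_sim)
    reps = []
    for cid in np.unique(clusters):
        members = np.where(clusters == cid)[0]
        best = min(members, key=lambda i: (-max_proba[i], survivor_ids[i]))
        reps.append(survivor_ids[best])
    return sorted(reps), clusters


# ---------------------------------------------------------------------------
# the funnel
# ---------------------------------------------------------------------------

def run_funnel(
    library: Sequence[CompoundRecord],
    bundles: Sequence,
    known_active_fps: np.ndarray,
    config: Optional[FunnelConfig] = None,
    feature_fn=None,
) -> FunnelReport:
    """Apply the full cascade to a standardized library.

    ``bundles`` are trained :class:`~cypscreen.modeling.ModelBundle` objects
    (canonically four: two sources x two feature panels).  ``feature_fn``
    maps (records, panel name) to a feature matrix; by default ECFP4 and the
    physicochemical panel are computed on the fly.

    The report carries per-stage survivor id lists, per-compound first
    failure reasons, and the final ranked shortlist for manual inspection.
    """
    from . import chemspace

    cfg = config or FunnelConfig()
    report = FunnelReport()
    ids = [r.compound_id for r in library]
    mols = {r.compound_id: Chem.MolFromSmiles(r.smiles_std) for r in library}
    bad = sorted(cid for cid, m in mols.items() if m is None)
    if bad:
        raise ValueError(f"unparseable standardized SMILES for {bad[:5]}")

    # stage 1: rule of five
    reasons = {}
    s1 = []
    for cid in ids:
        if ro5_filter(mols[cid]):
            s1.append(cid)
        else:
            reasons[cid] = "ro5-violations"
    report.add("ro5", ids, s1, reasons)

    # stage 2: CYP motif
    reasons = {}
    s2 = []
    for cid in s1:
        if cyp_motif_filter(mols[cid], cfg.motif_smarts):
            s2.append(cid)
        else:
            reasons[cid] = "no-cyp-motif"
    report.add("cyp_motif", s1, s2, reasons)

    # stage 3: ensemble rank/probability gate
    rec_by_id = {r.compound_id: r for r in library}
    s2_records = [rec_by_id[cid] for cid in s2]
    if feature_fn is None:
        def feature_fn(records, panel):
            if panel == "ecfp4_2048":
                return chemspace.ecfp4_block(records).matrix
            block = chemspace.physchem_block(records)
            return block.matrix

    if s2_records:
        proba = np.column_stack(
            [b.predict_proba_active(feature_fn(s2_records, b.panel)) for b in bundles]
        )
    else:
        proba = np.zeros((0, len(bundles)))
    s3 = ensemble_gate(s2, proba, top_n=cfg.top_n, p_min=cfg.p_min)
    max_proba = {cid: float(p) for cid, p in zip(s2, proba.max(axis=1))} if s2 else {}
    report.max_proba = max_proba
    report.add(
        "ensemble_gate", s2, s3,
        {cid: "below-rank-or-probability-gate" for cid in s2 if cid not in set(s3)},
    )

    # stage 4: novelty vs known actives
    s3_fps = np.vstack([ecfp4(rec_by_id[cid].smiles_std) for cid in s3]) if s3 else np.zeros((0, 2048))
    s4, nn_sim = novelty_filter(s3_fps, s3, known_active_fps, cfg.novelty_max_sim)
    report.add(
        "novelty", s3, s4,
        {cid: "similar-to-known-active" for cid in s3 if cid not in set(s4)},
    )

    # stage 5: liabilities
    reasons = {}
    s5 = []
    for cid in s4:
        ok, why = liability_filter(mols[cid], cfg)
        if ok:
            s5.append(cid)
        else:
            reasons[cid] = ",".join(why)
    report.add("liability", s4, s5, reasons)

    # stage 6: diversity clustering
    s5_fps = np.vstack([ecfp4(rec_by_id[cid].smiles_std) for cid in s5]) if s5 else np.zeros((0, 2048))
    s6, _ = diversity_select(s5, s5_fps, [max_proba[cid] for cid in s5], cfg.diversity_sim)
    report.add(
        "diversity", s5, s6,
        {cid: "cluster-representative-elsewhere" for cid in s5 if cid not in set(s6)},
    )

    report.shortlist = sorted(
        ((cid, max_proba[cid]) for cid in s6), key=lambda t: (-t[1], t[0])
    )
    report.validate()
    return report
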