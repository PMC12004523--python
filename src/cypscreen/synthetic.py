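"""Synthetic bioactivity datasets and screening libraries.

Real inputs to this kind of campaign are curated database extracts (a
potency-annotated set and a large imbalanced assay-score set) plus a
multi-million-compound purchasable library.  This module generates
stand-ins with the statistical structure the analysis relies on:

* molecules built from a scaffold x substituent grammar (azole-, pyridine-
  and plain-aromatic ring systems decorated with small acyclic fragments),
  which guarantees chemical validity, a controllable Murcko-scaffold
  census (many analogs per scaffold), and passage through the curation
  element/weight window by construction;
* a **planted structure-activity rule**: a molecule is truly active iff it
  matches a configurable SMARTS (default: an aromatic imidazole, so planted
  actives also pass the screening CYP-motif gate); observed labels flip
  with a configurable noise rate;
* two source profiles mirroring the label semantics of the real databases:
  ``balanced_potency`` (continuous pIC50-like values, about 1.2:1
  active:inactive) and ``imbalanced_score`` (0-100 integer scores, about
  1:11);
* a screening-library generator whose decoys lack the planted rule but can
  carry the CYP motif (so the motif gate is non-trivial), with ground-truth
  flags kept in a separate sidecar so the pipeline cannot see them.

Generation is fully deterministic: identical config + seed produce
byte-identical output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from scipy.stats import truncnorm

from .curation import standardize_structure
from .records import CompoundRecord, Label, Source

# Ring-system cores with two attachment points.  Bare cores weigh >= 195 Da
# and the lightest substituent pair adds >= 56 Da, so every assembled
# molecule clears the 250 Da curation floor; the heaviest combinations stay
# near 450 Da, inside both the curation ceiling and the rule-of-five window.
ACTIVE_CORES = (
    "O=c1cc(-n2ccnc2)c2cc([*:1])c([*:2])cc2o1",        # imidazol-1-yl coumarin
    "[*:1]c1ccc(C(=O)Nc2ccc(-n3ccnc3)cc2)c([*:2])c1",  # imidazolylphenyl benzamide
    "[*:1]c1ccc(-c2csc(-n3ccnc3)n2)cc1[*:2]",          # imidazolyl-thiazolyl-benzene
    "O=C(Nc1ccc(-n2ccnc2)cc1)c1cc([*:1])c([*:2])o1",   # furan-2-carboxanilide w/ imidazole
    "[*:1]c1ccc2nc(-n3ccnc3)sc2c1[*:2]",               # imidazolyl-benzothiazole
)

INACTIVE_CORES = (
    "O=c1cc(-c2ccccc2)c2cc([*:1])c([*:2])cc2o1",       # 4-phenylcoumarin
    "[*:1]c1ccc(C(=O)Nc2ccccc2C(N)=O)c([*:2])c1",      # anthranilamide benzamide
    "[*:1]c1ccc(-c2csc(-c3ccccc3)n2)cc1[*:2]",         # 2,4-diphenylthiazole
    "[*:1]c1ccc(Oc2ccc(C(=O)NC)cc2)c([*:2])c1",        # diphenyl-ether amide
    "O=c1[nH]c2cc([*:1])c([*:2])cc2c(=O)n1-c1ccccc1",  # 3-phenylquinazoline-2,4-dione
    "[*:1]c1ccc(S(=O)(=O)Nc2ccccc2)c([*:2])c1",        # benzenesulfonanilide
)

# pyridine-bearing decoys: pass the CYP-motif gate without the planted azole
MOTIF_DECOY_CORES = (
    "[*:1]c1ccc(-c2ccnc(-c3ccccc3)c2)cc1[*:2]",        # 2-phenyl-4-arylpyridine
    "O=c1cc(-c2ccncc2)c2cc([*:1])c([*:2])cc2o1",       # 4-pyridylcoumarin
    "[*:1]c1ccc(C(=O)Nc2ccncc2)c([*:2])c1",            # N-pyridyl benzamide
)

SUBSTITUENTS = (
    "[*:1]CC",
    "[*:1]C(C)C",
    "[*:1]OC",
    "[*:1]OCC",
    "[*:1]Cl",
    "[*:1]C(=O)NC",
    "[*:1]NC(C)=O",
    "[*:1]CO",
    "[*:1]OCCOC",
    "[*:1]C(=O)OC",
    "[*:1]C(F)(F)F",
    "[*:1]CC#N",
    "[*:1]S(C)(=O)=O",
    "[*:1]C(=O)N(C)C",
    "[*:1]CCO",
    "[*:1]OC(C)C",
)

# substituent pool for the "foreign source" variant: same cores, shifted
# decoration distribution, emulating cross-source chemical-space drift
FOREIGN_SUBSTITUENTS = (
    "[*:1]CCC",
    "[*:1]OCCC",
    "[*:1]C(C)(C)C",
    "[*:1]N(C)C(C)=O",
    "[*:1]C(=O)NCC",
    "[*:1]CCC#N",
    "[*:1]S(=O)(=O)CC",
    "[*:1]C(=O)OCC",
    "[*:1]OCC(C)C",
    "[*:1]C(=O)NC(C)C",
    "[*:1]CC(C)O",
    "[*:1]OCC(F)(F)F",
    "[*:1]CC(C)C",
    "[*:1]OCC#N",
    "[*:1]C(=O)NCCO",
    "[*:1]CCOC",
    "[*:1]N(CC)C(C)=O",
    "[*:1]C(=O)N(CC)CC",
    "[*:1]S(=O)(=O)N(C)C",
    "[*:1]CCS(C)(=O)=O",
    "[*:1]OCCCO",
    "[*:1]C(C)CC",
    "[*:1]CC(F)(F)F",
    "[*:1]C(=O)NCC#N",
    "[*:1]CCCO",
    "[*:1]OCCF",
    "[*:1]CCCC",
    "[*:1]C(=O)NCCOC",
    "[*:1]CCF",
)

DEFAULT_PLANTED_RULE = "c1cncn1"  # aromatic imidazole


@dataclass
class SyntheticConfig:
    """Study conditions for one generated dataset.

    ``n_active``/``n_inactive`` are the truly-active / truly-inactive
    structure counts (the planted rule decides truth; ``label_noise`` flips
    the *observed* label).  The default profile ratios mirror the two real
    sources this generator stands in for: a near-balanced potency source
    (~1.2:1) and a strongly imbalanced score source (~1:11).
    """

    n_active: int = 327
    n_inactive: int = 273
    source_profile: str = "balanced_potency"  # or "imbalanced_score"
    planted_rule: str = DEFAULT_PLANTED_RULE
    label_noise: float = 0.0
    n_scaffolds: int = 10
    decorations_per_scaffold: Optional[int] = None
    excluded_band_fraction: float = 0.0  # score-source records pushed to 5-30
    foreign: bool = False
    seed: int = 42

    def __post_init__(self):
        if not (0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must lie in [0, 0.5)")
        if self.source_profile not in ("balanced_potency", "imbalanced_score"):
            raise ValueError(f"unknown source profile {self.source_profile!r}")
        if self.n_active < 1 or self.n_inactive < 1:
            raise ValueError("need at least one molecule per class")
        if self.decorations_per_scaffold is not None:
            total = self.n_active + self.n_inactive
            self.n_scaffolds = max(2, int(np.ceil(total / self.decorations_per_scaffold)))

    @property
    def source(self) -> Source:
        return Source.POTENCY if self.source_profile == "balanced_potency" else Source.SCORE

    @classmethod
    def imbalanced(cls, n_total: int = 600, **kw) -> "SyntheticConfig":
        """Score-source profile at the ~1:11 active:inactive ratio."""
        n_active = max(1, round(n_total / 12))
        return cls(
            n_active=n_active,
            n_inactive=n_total - n_active,
            source_profile="imbalanced_score",
            **kw,
        )

    @classmethod
    def balanced(cls, n_total: int = 600, **kw) -> "SyntheticConfig":
        """Potency-source profile at the ~1.2:1 active:inactive ratio."""
        n_active = round(n_total * 1.2 / 2.2)
        return cls(
            n_active=n_active,
            n_inactive=n_total - n_active,
            source_profile="balanced_potency",
            **kw,
        )


def _assemble(core: str, sub1: str, sub2: str) -> Optional[str]:
    """Zip a two-slot core with two substituent fragments; canonical SMILES."""
    c = Chem.MolFromSmiles(core)
    a = Chem.MolFromSmiles(sub1)
    b = Chem.MolFromSmiles(sub2.replace("[*:1]", "[*:2]"))
    if c is None or a is None or b is None:
        return None
    try:
        mol = Chem.molzip(Chem.CombineMols(Chem.CombineMols(c, a), b))
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def _allocate(total: int, n_bins: int) -> list:
    """Spread `total` items over `n_bins` as evenly as possible."""
    base, extra = divmod(total, n_bins)
    return [base + (1 if i < extra else 0) for i in range(n_bins)]


def _build_class(
    cores: Sequence[str],
    n_cores: int,
    n_molecules: int,
    substituents: Sequence[str],
    rng: np.random.RandomState,
    seen: set,
) -> list:
    """Generate standardized SMILES for one class, cycling cores and drawing
    distinct substituent pairs per core."""
    n_cores = max(1, min(n_cores, len(cores)))
    combos = list(itertools.product(range(len(substituents)), repeat=2))
    out = []
    for core_idx, quota in enumerate(_allocate(n_molecules, n_cores)):
        core = cores[core_idx]
        order = rng.permutation(len(combos))
        taken = 0
        for pos in order:
            if taken >= quota:
                break
            i, j = combos[pos]
            raw = _assemble(core, substituents[i], substituents[j])
            if raw is None:
                continue
            smiles, reason = standardize_structure(raw)
            if reason is not None or smiles in seen:
                continue
            seen.add(smiles)
            out.append(smiles)
            taken += 1
        if taken < quota:
            raise ValueError(
                f"substituent grammar exhausted: core {core_idx} produced "
                f"{taken}/{quota} unique molecules"
            )
    return out


def _potency_values(n: int, active: bool, rng: np.random.RandomState) -> np.ndarray:
    """pIC50-like values consistent with the observed label.

    Actives ~ Normal(7.0, 0.7) truncated to >= 6; inactives ~ Normal(5.0,
    0.6) truncated to < 6, so value-based labeling reproduces the label.
    """
    if active:
        return truncnorm.rvs((6.0 - 7.0) / 0.7, np.inf, loc=7.0, scale=0.7, size=n, random_state=rng)
    return truncnorm.rvs(-np.inf, (6.0 - 5.0) / 0.6, loc=5.0, scale=0.6, size=n, random_state=rng)


def generate_labeled_dataset(config: SyntheticConfig) -> tuple:
    """Generate a labeled bioactivity dataset plus its ground-truth sidecar.

    Returns ``(records, truth)`` where ``truth`` maps compound_id to
    ``{"true_active": bool}``.  Records carry observed labels and
    label-consistent activity payloads; every SMILES is already in standard
    canonical form, so curation is a no-op apart from bookkeeping.
    """
    rng = np.random.RandomState(config.seed)
    rule = Chem.MolFromSmarts(config.planted_rule)
    if rule is None:
        raise ValueError(f"unparseable planted rule {config.planted_rule!r}")
    subs = FOREIGN_SUBSTITUENTS if config.foreign else SUBSTITUENTS

    total = config.n_active + config.n_inactive
    cores_active = max(1, round(config.n_scaffolds * config.n_active / total))
    cores_inactive = max(1, config.n_scaffolds - cores_active)

    seen: set = set()
    active_smiles = _build_class(ACTIVE_CORES, cores_active, config.n_active, subs, rng, seen)
    inactive_smiles = _build_class(INACTIVE_CORES, cores_inactive, config.n_inactive, subs, rng, seen)

    for smi in active_smiles:
        if not Chem.MolFromSmiles(smi).HasSubstructMatch(rule):
            raise ValueError(f"planted rule does not match generated active {smi!r}")
    for smi in inactive_smiles:
        if Chem.MolFromSmiles(smi).HasSubstructMatch(rule):
            raise ValueError(f"planted rule matches generated inactive {smi!r}")

    prefix = "pot" if config.source_profile == "balanced_potency" else "sco"
    records, truth = [], {}
    all_smiles = [(s, True) for s in active_smiles] + [(s, False) for s in inactive_smiles]
    flips = rng.uniform(size=len(all_smiles)) < config.label_noise
    observed = [ta != bool(f) for (_, ta), f in zip(all_smiles, flips)]

    if config.source_profile == "balanced_potency":
        values = np.empty(len(all_smiles))
        act_idx = [i for i, o in enumerate(observed) if o]
        inact_idx = [i for i, o in enumerate(observed) if not o]
        values[act_idx] = _potency_values(len(act_idx), True, rng)
        values[inact_idx] = _potency_values(len(inact_idx), False, rng)
    else:
        values = np.zeros(len(all_smiles))
        for i, o in enumerate(observed):
            values[i] = rng.randint(40, 101) if o else 0
        if config.excluded_band_fraction > 0:
            push = rng.uniform(size=len(all_smiles)) < config.excluded_band_fraction
            for i in np.where(push)[0]:
                values[i] = rng.randint(5, 31)

    for i, ((smiles, true_active), _obs) in enumerate(zip(all_smiles, observed)):
        cid = f"{prefix}-{i:05d}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles_raw=smiles,
                smiles_std=smiles,
                source=config.source,
                activity_value=float(values[i]),
                label=Label.UNLABELED,
            )
        )
        truth[cid] = {"true_active": true_active}
    return records, truth


def generate_screening_library(
    n_decoys: int,
    n_planted: int,
    config: Optional[SyntheticConfig] = None,
    motif_decoy_fraction: float = 0.3,
) -> tuple:
    """Generate an unlabeled screening library with planted actives.

    Decoys never match the planted rule; a ``motif_decoy_fraction`` of them
    are drawn from pyridine-bearing cores so the CYP-motif gate removes some
    but not all decoys.  Planted actives carry the rule (and hence, for the
    default imidazole rule, pass the motif gate).  Ground truth lives in the
    returned sidecar, not on the records.

    Returns ``(records, truth)`` with ``truth[compound_id] =
    {"planted": bool, "has_motif": bool}``.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.RandomState(cfg.seed + 101)
    rule = Chem.MolFromSmarts(cfg.planted_rule)
    subs = FOREIGN_SUBSTITUENTS if cfg.foreign else SUBSTITUENTS

    n_motif = int(round(n_decoys * motif_decoy_fraction))
    n_plain = n_decoys - n_motif
    seen: set = set()
    planted = (
        _build_class(ACTIVE_CORES, len(ACTIVE_CORES), n_planted, subs, rng, seen)
        if n_planted
        else []
    )
    plain = (
        _build_class(INACTIVE_CORES, len(INACTIVE_CORES), n_plain, subs, rng, seen)
        if n_plain
        else []
    )
    motif = (
        _build_class(MOTIF_DECOY_CORES, len(MOTIF_DECOY_CORES), n_motif, subs, rng, seen)
        if n_motif
        else []
    )

    for smi in plain + motif:
        if Chem.MolFromSmiles(smi).HasSubstructMatch(rule):
            raise ValueError(f"decoy matches planted rule: {smi!r}")

    records, truth = [], {}
    entries = [(s, True) for s in planted] + [(s, False) for s in plain + motif]
    order = rng.permutation(len(entries))
    motif_patterns = [Chem.MolFromSmarts(s) for s in ("c1cncn1", "c1cnnn1", "c1ncnn1", "c1ccncc1")]
    for k, idx in enumerate(order):
        smiles, is_planted = entries[idx]
        cid = f"lib-{k:06d}"
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles_raw=smiles,
                smiles_std=smiles,
                source=Source.LIBRARY,
                label=Label.UNLABELED,
            )
        )
        mol = Chem.MolFromSmiles(smiles)
        truth[cid] = {
            "planted": is_planted,
            "has_motif": any(mol.HasSubstructMatch(p) for p in motif_patterns),
        }
    return records, truth


def scaffold_clustering_strength(records: Sequence[CompoundRecord], min_members: int = 10) -> dict:
    """Summary of how strongly the dataset clusters into Murcko scaffolds."""
    from .chemspace import scaffold_census

    census = scaffold_census(records)
    sizes = sorted((sum(c) for c in census.values()), reverse=True)
    return {
        "n_molecules": int(sum(sizes)),
        "n_scaffolds": len(census),
        "n_scaffolds_with_min_members": sum(1 for s in sizes if s >= min_members),
        "largest_scaffold": sizes[0] if sizes else 0,
    }
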