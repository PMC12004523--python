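"""Featurization and chemical-space analysis.

Three feature panels are provided:

``ecfp4_2048``
    Extended-connectivity fingerprints, radius 2, folded to 2048 bits -- the
    similarity currency of the whole pipeline (Tanimoto comparisons, Butina
    clustering, novelty filtering) and one of the two model input panels.
``physchem_2d``
    A pinned panel of 2D physicochemical descriptors (manifest shipped with
    the package; the exact count is toolkit-version dependent, so tests
    assert manifest consistency rather than a literal number).  ``Ipc`` is
    excluded from the manifest because it overflows for large molecules.
``pca_panel_13``
    The 13 interpretable properties used for chemical-space PCA maps:
    element counts, size, H-bonding, lipophilicity, polarity, aromaticity,
    charge, ring count and sp3 character.

Scaffold analysis uses plain Bemis-Murcko frameworks (ring systems plus
linkers, side chains removed; no atom/bond abstraction); acyclic molecules
map to the empty scaffold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from rdkit.ML.Descriptors.MoleculeDescriptors import MolecularDescriptorCalculator

from .records import CompoundRecord, Label

_N_BITS = 2048
_morgan = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=_N_BITS)

PCA_PANEL_13 = [
    "n_nitrogen",
    "n_oxygen",
    "n_chiral_centers",
    "mol_weight",
    "n_heavy_atoms",
    "n_hba",
    "n_hbd",
    "logp",
    "tpsa",
    "n_aromatic_atoms",
    "sum_formal_charge",
    "n_rings",
    "fraction_csp3",
]


def physchem_manifest() -> list:
    """Ordered descriptor names of the pinned 2D physicochemical panel."""
    text = resources.files("cypscreen.data").joinpath("physchem_manifest.json")
    return json.loads(text.read_text())["descriptors"]


@dataclass
class FeatureBlock:
    """A dense feature matrix aligned with an ordered compound-id list."""

    compound_ids: list
    matrix: np.ndarray
    panel: str
    manifest: list = field(default_factory=list)

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.matrix.shape[0] != len(self.compound_ids):
            raise ValueError("row count != number of compound ids")
        if self.manifest and self.matrix.shape[1] != len(self.manifest):
            raise ValueError("column count != manifest length")

    def impute_nonfinite_(self, medians: Optional[np.ndarray] = None) -> np.ndarray:
        """Replace non-finite entries column-wise, in place.

        Uses the supplied medians (from a training block) or this block's own
        finite column medians.  Returns the medians used so a test/screening
        block can reuse the training statistics.
        """
        X = self.matrix
        if medians is None:
            with np.errstate(invalid="ignore"):
                masked = np.where(np.isfinite(X), X, np.nan)
                medians = np.nanmedian(masked, axis=0)
            medians = np.where(np.isfinite(medians), medians, 0.0)
        bad = ~np.isfinite(X)
        if bad.any():
            X[bad] = np.broadcast_to(medians, X.shape)[bad]
        return medians


def _mol(smiles: str, context: str = "") -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES{': ' + context if context else ''}: {smiles!r}")
    return mol


def ecfp4(smiles_std: str, context: str = "") -> np.ndarray:
    """2048-bit ECFP4 (Morgan radius-2) fingerprint as a uint8 0/1 vector."""
    fp = _morgan.GetFingerprint(_mol(smiles_std, context))
    arr = np.zeros(_N_BITS, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def ecfp4_block(records: Sequence[CompoundRecord]) -> FeatureBlock:
    ids = [r.compound_id for r in records]
    mat = np.vstack([ecfp4(r.smiles_std, r.compound_id) for r in records]) if records else np.zeros((0, _N_BITS), np.uint8)
    return FeatureBlock(ids, mat, "ecfp4_2048", [f"bit_{i}" for i in range(_N_BITS)])


def physchem_panel(smiles_std: str, context: str = "") -> np.ndarray:
    """Pinned 2D physicochemical descriptor vector (manifest order)."""
    calc = _physchem_calculator()
    vals = calc.CalcDescriptors(_mol(smiles_std, context))
    return np.asarray(vals, dtype=np.float64)


_calc_cache: dict = {}


def _physchem_calculator() -> MolecularDescriptorCalculator:
    if "calc" not in _calc_cache:
        _calc_cache["calc"] = MolecularDescriptorCalculator(physchem_manifest())
    return _calc_cache["calc"]


def physchem_block(records: Sequence[CompoundRecord]) -> FeatureBlock:
    manifest = physchem_manifest()
    ids = [r.compound_id for r in records]
    mat = (
        np.vstack([physchem_panel(r.smiles_std, r.compound_id) for r in records])
        if records
        else np.zeros((0, len(manifest)))
    )
    return FeatureBlock(ids, mat, "physchem_2d", manifest)


def pca_panel_13(smiles_std: str) -> np.ndarray:
    """The fixed 13-property vector used for chemical-space PCA maps."""
    mol = _mol(smiles_std)
    n_n = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 7)
    n_o = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 8)
    n_chiral = len(Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False))
    return np.array(
        [
            n_n,
            n_o,
            n_chiral,
            Descriptors.MolWt(mol),
            mol.GetNumHeavyAtoms(),
            rdMolDescriptors.CalcNumHBA(mol),
            rdMolDescriptors.CalcNumHBD(mol),
            Crippen.MolLogP(mol),
            rdMolDescriptors.CalcTPSA(mol),
            sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()),
            Chem.GetFormalCharge(mol),
            rdMolDescriptors.CalcNumRings(mol),
            rdMolDescriptors.CalcFractionCSP3(mol),
        ],
        dtype=np.float64,
    )


def pca_panel_block(records: Sequence[CompoundRecord]) -> FeatureBlock:
    ids = [r.compound_id for r in records]
    mat = (
        np.vstack([pca_panel_13(r.smiles_std) for r in records])
        if records
        else np.zeros((0, 13))
    )
    return FeatureBlock(ids, mat, "pca_panel_13", list(PCA_PANEL_13))


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a&b|/|a|b| of two equal-length bit vectors.

    Two all-zero vectors are defined as identical (similarity 1.0); an
    all-zero vector against any nonzero vector scores 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("fingerprint length mismatch")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto between rows of two binary matrices (n_q x n_r)."""
    q = np.asarray(query, dtype=np.float64)
    r = np.asarray(reference, dtype=np.float64)
    inter = q @ r.T
    union = q.sum(1)[:, None] + r.sum(1)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def nn_profile(
    query_fps: np.ndarray,
    reference_fps: np.ndarray,
    thresholds: Optional[np.ndarray] = None,
) -> tuple:
    """Nearest-neighbor similarity profile of a query set against a reference.

    For each query compound the maximum Tanimoto similarity to the reference
    set is computed; the profile reports, on a threshold grid, the proportion
    of query compounds whose nearest neighbor is at least that similar.  The
    curve is monotone non-increasing in the threshold.

    Returns ``(thresholds, proportions, nn_similarities)``.
    """
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    thresholds = np.asarray(thresholds, dtype=float)
    if len(query_fps) == 0:
        return thresholds, np.zeros_like(thresholds), np.zeros(0)
    if len(reference_fps) == 0:
        nn = np.zeros(len(query_fps))
    else:
        nn = tanimoto_matrix(query_fps, reference_fps).max(axis=1)
    props = np.array([(nn >= t).mean() for t in thresholds])
    return thresholds, props, nn


def murcko_scaffold(smiles_std: str) -> str:
    """Canonical Bemis-Murcko framework; '' for acyclic molecules."""
    mol = _mol(smiles_std)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def scaffold_census(records: Sequence[CompoundRecord]) -> dict:
    """Per-scaffold (n_active, n_inactive) counts; every molecule maps to
    exactly one scaffold, so the counts sum to the dataset size.  Intended
    for curated datasets where each record is active or inactive; any other
    label is tallied as inactive."""
    census: dict = {}
    for rec in records:
        scaf = murcko_scaffold(rec.smiles_std)
        n_act, n_inact = census.get(scaf, (0, 0))
        if rec.label is Label.ACTIVE:
            n_act += 1
        else:
            n_inact += 1
        census[scaf] = (n_act, n_inact)
    return census


def top_scaffolds(census: dict, min_members: int = 10) -> list:
    """Scaffolds with at least ``min_members`` molecules, largest first."""
    items = [(s, c) for s, c in census.items() if sum(c) >= min_members]
    return sorted(items, key=lambda x: (-sum(x[1]), x[0]))


def pca_project(block: FeatureBlock, k: int = 2) -> tuple:
    """PCA scores of a feature block after z-scoring each column.

    Constant columns are dropped before scaling (their variance is zero and
    they carry no chemical-space information).  Components are ordered by
    decreasing explained variance.

    Returns ``(scores n x k, explained_variance_ratio)``.
    """
    from sklearn.decomposition import PCA

    X = np.asarray(block.matrix, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("feature matrix contains non-finite values; impute first")
    keep = X.std(axis=0) > 0
    Xk = X[:, keep]
    Xz = (Xk - Xk.mean(axis=0)) / Xk.std(axis=0)
    k = min(k, Xz.shape[1], Xz.shape[0])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(Xz)
    return scores, pca.explained_variance_ratio_
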