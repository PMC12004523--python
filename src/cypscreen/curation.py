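"""Structure standardization and activity labeling.

Raw bioactivity records arrive as (id, SMILES, source, value) rows.  Curation
turns them into a clean modeling dataset in four stages:

1. **standardize** -- strip salt/solvent components (keep the largest organic
   fragment), neutralize charges, pick the canonical tautomer, drop all
   stereochemistry, and emit canonical SMILES.  Unparseable or empty inputs
   are rejected with a reason, never an exception.
2. **element/weight filter** -- keep parent structures built from common
   organic elements (H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I) with average
   molecular weight in the inclusive range 250-900 Da.
3. **label** -- potency-source records are active iff their pIC50-like value
   is >= 6 (i.e. potency <= 1 uM); score-source records are inactive at
   score 0, active at scores 40-100, and excluded otherwise.
4. **deduplicate** -- records are grouped on canonical SMILES; groups whose
   members agree keep one representative, groups with conflicting labels are
   dropped entirely.

The fixed stage order (strip -> neutralize -> tautomer -> de-stereo ->
canonicalize) makes tautomer selection independent of counter-ions, and the
whole transform is idempotent: re-standardizing a standardized SMILES is a
no-op.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import CompoundRecord, CurationReport, Label, Source

RDLogger.DisableLog("rdApp.*")

#: Elements retained by the curation filter.
ALLOWED_ELEMENTS = frozenset(
    ["H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"]
)

#: Inclusive average-molecular-weight window (Da) for the parent structure.
MW_MIN = 250.0
MW_MAX = 900.0

#: Potency threshold on the -log10(M) scale; >= 6 means IC50 <= 1 uM.
POTENCY_ACTIVE_MIN = 6.0

# Rejection reasons
UNPARSEABLE = "unparseable"
EMPTY_AFTER_STRIPPING = "empty-after-stripping"
MW_BELOW = "mw-below-range"
MW_ABOVE = "mw-above-range"
DISALLOWED_ELEMENT = "disallowed-element"
SCORE_EXCLUDED_BAND = "score-in-excluded-band"
MISSING_ACTIVITY = "missing-activity-value"
CONFLICTING_LABELS = "conflicting-labels"
DUPLICATE = "duplicate-structure"

_fragment_chooser = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)
_uncharger = rdMolStandardize.Uncharger()
_tautomerizer = rdMolStandardize.TautomerEnumerator()


def standardize_structure(
    smiles_raw: str,
    pre_hook: Optional[Callable[[Chem.Mol], Optional[Chem.Mol]]] = None,
) -> tuple:
    """Standardize a raw SMILES to its canonical parent form.

    Parameters
    ----------
    smiles_raw:
        Input SMILES, possibly multi-component (salts, solvents).
    pre_hook:
        Optional callable applied to the parsed molecule before any other
        step; extension point for site-specific washing rules.  Returning
        ``None`` rejects the molecule.

    Returns
    -------
    (smiles_std, reason):
        ``(canonical SMILES, None)`` on success, ``(None, reason)`` on
        rejection.  Never raises on malformed input.
    """
    if not smiles_raw or not smiles_raw.strip():
        return None, UNPARSEABLE
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        return None, UNPARSEABLE
    if pre_hook is not None:
        mol = pre_hook(mol)
        if mol is None:
            return None, EMPTY_AFTER_STRIPPING
    try:
        mol = _fragment_chooser.choose(mol)
        if mol is None or mol.GetNumAtoms() == 0:
            return None, EMPTY_AFTER_STRIPPING
        mol = _uncharger.uncharge(mol)
        mol = _tautomerizer.Canonicalize(mol)
        Chem.RemoveStereochemistry(mol)
        smiles = Chem.MolToSmiles(mol)
    except Exception:  # pragma: no cover - defensive; RDKit edge cases
        return None, UNPARSEABLE
    if not smiles:
        return None, EMPTY_AFTER_STRIPPING
    return smiles, None


def element_weight_filter(smiles_std: str) -> tuple:
    """Pure predicate: (passes, reason) for the element and MW rules.

    Molecular weight is the average (isotope-abundance-weighted) weight of
    the standardized parent; the 250 and 900 Da boundaries pass.
    """
    mol = Chem.MolFromSmiles(smiles_std)
    if mol is None:
        return False, UNPARSEABLE
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in ALLOWED_ELEMENTS:
            return False, DISALLOWED_ELEMENT
    mw = Descriptors.MolWt(mol)
    if mw < MW_MIN:
        return False, MW_BELOW
    if mw > MW_MAX:
        return False, MW_ABOVE
    return True, None


def label_by_potency(pchembl: float) -> Label:
    """Binary activity label from a pIC50-like potency: active iff >= 6."""
    return Label.ACTIVE if pchembl >= POTENCY_ACTIVE_MIN else Label.INACTIVE


def label_by_score(score: int) -> Label:
    """Label from a 0-100 integer assay score.

    0 -> inactive, 40-100 -> active.  Everything else (the ambiguous
    mid-band) is excluded from modeling.
    """
    if score == 0:
        return Label.INACTIVE
    if 40 <= score <= 100:
        return Label.ACTIVE
    return Label.EXCLUDED


def label_record(record: CompoundRecord) -> Label:
    if record.source is Source.LIBRARY:
        return Label.UNLABELED
    if record.activity_value is None:
        return Label.EXCLUDED
    if record.source is Source.POTENCY:
        return label_by_potency(float(record.activity_value))
    return label_by_score(int(round(record.activity_value)))


def deduplicate(records: Sequence[CompoundRecord]) -> tuple:
    """Collapse records sharing a canonical SMILES.

    Groups with a single distinct label keep one representative (first in
    ``compound_id`` sort order); groups with conflicting labels are removed
    entirely.  Output is ordered by canonical SMILES, so the result depends
    only on the input *set*.

    Returns ``(kept_records, reasons)`` where reasons counts drops by cause.
    """
    groups: dict = {}
    for rec in records:
        groups.setdefault(rec.smiles_std, []).append(rec)
    kept = []
    reasons = {CONFLICTING_LABELS: 0, DUPLICATE: 0}
    for smiles in sorted(groups):
        members = sorted(groups[smiles], key=lambda r: r.compound_id)
        labels = {m.label for m in members}
        if len(labels) > 1:
            reasons[CONFLICTING_LABELS] += len(members)
        else:
            kept.append(members[0])
            reasons[DUPLICATE] += len(members) - 1
    reasons = {k: v for k, v in reasons.items() if v}
    return kept, reasons


def cross_source_overlap(
    set_a: Iterable[CompoundRecord], set_b: Iterable[CompoundRecord]
) -> tuple:
    """Count canonical structures shared between two curated sets.

    Returns ``(n_shared_active, n_shared_inactive)`` where a structure counts
    if it carries that label in *both* sources.  Structures labeled
    differently across sources are reported separately by
    :func:`cross_source_consistency` for manual review.
    """
    a = {r.smiles_std: r.label for r in set_a}
    b = {r.smiles_std: r.label for r in set_b}
    shared = set(a) & set(b)
    n_act = sum(1 for s in shared if a[s] is Label.ACTIVE and b[s] is Label.ACTIVE)
    n_inact = sum(
        1 for s in shared if a[s] is Label.INACTIVE and b[s] is Label.INACTIVE
    )
    return n_act, n_inact


def cross_source_consistency(
    set_a: Iterable[CompoundRecord], set_b: Iterable[CompoundRecord]
) -> list:
    """Structures labeled differently in the two sources (manual review list)."""
    a = {r.smiles_std: r.label for r in set_a}
    b = {r.smiles_std: r.label for r in set_b}
    return sorted(s for s in set(a) & set(b) if a[s] is not b[s])


def curate(
    records: Sequence[CompoundRecord],
    pre_hook: Optional[Callable] = None,
) -> tuple:
    """Run the full curation cascade on raw records.

    Returns ``(curated_records, CurationReport)``.  Curated records all have
    ``smiles_std`` set, pass the element/weight filter, carry a definite
    active/inactive label (library records stay unlabeled), and contain no
    duplicate canonical SMILES.
    """
    report = CurationReport()

    # stage 1: standardization
    standardized = []
    reasons: dict = {}
    for rec in records:
        smiles, reason = standardize_structure(rec.smiles_raw, pre_hook=pre_hook)
        if reason is not None:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        rec.smiles_std = smiles
        standardized.append(rec)
    report.add("standardize", len(records), len(standardized), reasons)

    # stage 2: element / molecular-weight filter
    filtered = []
    reasons = {}
    for rec in standardized:
        ok, reason = element_weight_filter(rec.smiles_std)
        if not ok:
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        filtered.append(rec)
    report.add("element_weight_filter", len(standardized), len(filtered), reasons)

    # stage 3: labeling (score mid-band and unlabellable records drop out)
    labeled = []
    reasons = {}
    for rec in filtered:
        rec.label = label_record(rec)
        if rec.label is Label.EXCLUDED:
            reason = (
                MISSING_ACTIVITY if rec.activity_value is None else SCORE_EXCLUDED_BAND
            )
            reasons[reason] = reasons.get(reason, 0) + 1
            continue
        labeled.append(rec)
    report.add("label", len(filtered), len(labeled), reasons)

    # stage 4: deduplication on canonical SMILES
    deduped, reasons = deduplicate(labeled)
    report.add("deduplicate", len(labeled), len(deduped), reasons)

    report.validate()
    return deduped, report
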