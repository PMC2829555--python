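"""Rule-based subfamily classification, substrate prediction and hybrid-gene
detection.

Subfamilies follow the four tetrapod-like classes seen across vertebrate
MIP repertoires: water-selective aquaporins, aquaglyceroporins (Glps), the
Aqp8-like water/urea channels, and the divergent "unorthodox" channels
(AQP11/12 lineage).  Rules are evaluated on the ar/R constriction tetrad
and the Froger P1-P5 match counts, in a fixed precedence order — the
Aqp8-like tetrad (His at the aromatic slot, Val/Ile at the His slot) is a
strict variant that would otherwise partially satisfy the water-selective
rules, so it is tested first.  Classification is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import (
    AROMATIC,
    AlignParams,
    DEFAULT_ALIGN,
    MipFeatureProfile,
)
from .io import GeneModel, ProteinRecord

SUBFAMILIES = ("aqp8-like", "water-selective", "glp", "unorthodox")


@dataclass(frozen=True)
class SubfamilyCall:
    label: str  # one of SUBFAMILIES or "unclassified"
    evidence: tuple[str, ...]
    score: float  # fraction of the winning class's rules satisfied


@dataclass(frozen=True)
class SubstratePrediction:
    permeants: frozenset[str]
    qualifier: str  # "predicted" or "none-in-oocytes"
    note: str = ""


@dataclass(frozen=True)
class HybridCall:
    is_hybrid: bool
    exon_assignments: tuple[tuple[str, float], ...]  # (label|"ambiguous", identity)
    breakpoints: tuple[int, ...]  # exon indices after which the label changes
    warning: str = ""


@dataclass(frozen=True)
class ConcordanceTable:
    table: pd.DataFrame
    agreement: float  # fraction of ids with exact permeant-set match


# ---------------------------------------------------------------------------
# Subfamily rules
# ---------------------------------------------------------------------------

def _class_rules(profile: MipFeatureProfile) -> dict[str, dict[str, bool]]:
    s1, s2, s3, s4 = profile.tetrad.residues()
    aq = profile.froger.aquaporin_count
    gl = profile.froger.glp_count
    tetrad_aqp8 = {
        "his_at_aromatic_slot": s1 == "H",
        "val_ile_at_histidine_slot": s2 in {"V", "I"},
        "arg_at_arginine_slot": s4 == "R",
    }
    tetrad_water = {
        "aromatic_at_slot1": s1 in AROMATIC,
        "his_at_slot2": s2 == "H",
        "arg_at_slot4": s4 == "R",
    }
    tetrad_glp = {
        "no_his_at_slot2": s2 is not None and s2 != "H",
        "aromatic_or_tyr_at_cys_slot": s3 in (AROMATIC | {"Y"}),
    }
    typical = (all(tetrad_aqp8.values()) or all(tetrad_water.values())
               or all(tetrad_glp.values()))
    return {
        "aqp8-like": tetrad_aqp8,
        "water-selective": {
            **tetrad_water,
            "aquaporin_froger_ge_glp": aq >= gl,
        },
        "glp": {
            **tetrad_glp,
            "glp_froger_ge_4": gl >= 4,
        },
        "unorthodox": {
            "atypical_tetrad": not typical,
            "aquaporin_froger_le_3": aq <= 3,
        },
    }


def classify_subfamily(
    profile: MipFeatureProfile, score_floor: float = 0.5
) -> SubfamilyCall:
    """Assign a subfamily label from an extracted feature profile.

    Classes are evaluated in fixed precedence order; the first class whose
    mandatory rules all hold wins.  If none holds fully, the best-scoring
    class is returned provided its rule-satisfaction fraction reaches
    ``score_floor`` (evidence then lists the violated rules); otherwise the
    label is ``unclassified``.  Profiles flagged non-MIP, or lacking both an
    NPA box and a tetrad mapping, are unclassified outright.
    """
    if profile.non_mip or profile.tetrad is None or profile.froger is None:
        return SubfamilyCall("unclassified", ("non_mip_profile",), 0.0)
    if not profile.npa_boxes:
        return SubfamilyCall("unclassified", ("no_npa_box",), 0.0)
    rules = _class_rules(profile)
    for label in SUBFAMILIES:
        checks = rules[label]
        if all(checks.values()):
            return SubfamilyCall(
                label, tuple(sorted(checks)), score=1.0
            )
    best_label, best_frac = None, -1.0
    for label in SUBFAMILIES:
        checks = rules[label]
        frac = sum(checks.values()) / len(checks)
        if frac > best_frac:
            best_label, best_frac = label, frac
    if best_frac >= score_floor:
        checks = rules[best_label]
        evidence = tuple(
            name if ok else f"violated:{name}"
            for name, ok in sorted(checks.items())
        )
        return SubfamilyCall(best_label, evidence, score=best_frac)
    return SubfamilyCall("unclassified", ("below_score_floor",), best_frac)


_SUBSTRATES = {
    "water-selective": (frozenset({"water"}), "predicted", ""),
    "glp": (frozenset({"water", "glycerol", "urea"}), "predicted", ""),
    "aqp8-like": (
        frozenset({"water", "urea"}),
        "predicted",
        "urea permeability varies within the Aqp8-like class",
    ),
    "unorthodox": (frozenset(), "none-in-oocytes",
                   "class shows no transport in oocytes"),
}


def predict_substrate(call: SubfamilyCall) -> SubstratePrediction:
    """Class-level permeant-set prediction.

    Intra-class exceptions (e.g. an Aqp8-like channel passing only water)
    are deliberately not modelled here; they surface in the concordance
    table against measured permeabilities.
    """
    if call.label == "unclassified":
        raise ValueError("cannot predict substrates for an unclassified call")
    permeants, qualifier, note = _SUBSTRATES[call.label]
    return SubstratePrediction(permeants, qualifier, note)


# ---------------------------------------------------------------------------
# Hybrid genes
# ---------------------------------------------------------------------------

def detect_hybrid_gene(
    model: GeneModel,
    exon_peptides: list[str],
    family_references: dict[str, list[ProteinRecord]],
    margin: float = 10.0,
    params: AlignParams | None = None,
    min_peptide: int = 10,
) -> HybridCall:
    """Detect chimeric genes from per-exon best-family assignment.

    Each translated exon peptide is scored by local-alignment percent
    identity against every reference family; an exon takes the best family's
    label when it beats the runner-up by at least ``margin`` identity
    points, else it is ``ambiguous``.  Contiguous same-label runs form
    blocks; the gene is called hybrid iff at least two non-ambiguous blocks
    carry different labels.
    """
    peptides = [p for p in exon_peptides if len(p) >= min_peptide]
    if len(peptides) < 2:
        raise ValueError("need >=2 exons with translatable peptides of >=10 aa")
    if len(exon_peptides) != len(model.exons):
        raise ValueError(
            f"{model.gene_id}: {len(exon_peptides)} peptides for "
            f"{len(model.exons)} exons"
        )
    aligner = (params or AlignParams(mode="local")).make_aligner()
    aligner.mode = "local"
    assignments: list[tuple[str, float]] = []
    for pep in exon_peptides:
        if len(pep) < min_peptide:
            assignments.append(("ambiguous", 0.0))
            continue
        scored = sorted(
            ((_best_local_identity(aligner, pep, refs), fam)
             for fam, refs in family_references.items()),
            reverse=True,
        )
        best_id, best_fam = scored[0]
        runner = scored[1][0] if len(scored) > 1 else 0.0
        if best_id - runner >= margin:
            assignments.append((best_fam, best_id))
        else:
            assignments.append(("ambiguous", best_id))
    blocks: list[str] = []
    breakpoints: list[int] = []
    last_label = None
    for i, (label, _) in enumerate(assignments):
        if label == "ambiguous":
            continue
        if label != last_label:
            blocks.append(label)
            if last_label is not None:
                breakpoints.append(i)
            last_label = label
    warning = ""
    if not blocks:
        warning = "all exons ambiguous; hybrid status not assessable"
    return HybridCall(
        is_hybrid=len(set(blocks)) >= 2 and len(blocks) >= 2,
        exon_assignments=tuple(assignments),
        breakpoints=tuple(breakpoints),
        warning=warning,
    )


def _best_local_identity(aligner, peptide: str,
                         refs: list[ProteinRecord]) -> float:
    best = 0.0
    for ref in refs:
        aln = aligner.align(peptide, ref.residues)[0]
        a, b = str(aln[0]), str(aln[1])
        cols = sum(1 for x, y in zip(a, b) if x != "-" or y != "-")
        ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        if cols:
            best = max(best, 100.0 * ident / cols)
    return best


# ---------------------------------------------------------------------------
# Prediction vs measurement concordance
# ---------------------------------------------------------------------------

def concordance_table(
    predictions: dict[str, SubstratePrediction],
    measurements: dict[str, frozenset[str] | set[str]],
) -> ConcordanceTable:
    """Compare predicted permeant sets against oocyte measurements.

    For every id present in both inputs the table reports the exact-set
    match and the subset relation (measured within predicted), plus the
    overall exact-agreement fraction.
    """
    ids = sorted(set(predictions) & set(measurements))
    if not ids:
        raise ValueError("no overlapping ids between predictions and measurements")
    rows = []
    for i in ids:
        pred = predictions[i].permeants
        meas = frozenset(measurements[i])
        rows.append({
            "id": i,
            "predicted": "+".join(sorted(pred)) or "none",
            "measured": "+".join(sorted(meas)) or "none",
            "exact_match": pred == meas,
            "subset_match": meas <= pred,
        })
    table = pd.DataFrame(rows).set_index("id")
    agreement = float(table["exact_match"].mean())
    return ConcordanceTable(table, agreement)
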