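"""Synthetic ground-truth data for every pipeline stage.

Generates MIP-like protein families with implanted class signatures, gene
models (including chimeric "hybrid" genes), oocyte swelling time-courses
forward-simulated from the Pf formula, and over-dispersed solute-uptake
counts — each paired with a :class:`SimulationTruth` record so pipeline
output can be joined back to the known truth.

Sequence model
--------------
Each class is described by a :class:`ClassSpec`: a pair of NPA triplets,
the four ar/R constriction residues, the five Froger P1-P5 residues, and a
six-TM block layout with loop lengths patterned on classical water
channels (263 residues; NPA-B Asn at 1-based 76, ar/R at 56/180/189/195,
NPA-E Asn at 192).  All classes descend from one deterministic ancestral
fill (hydrophobic residues in TM blocks, hydrophilic in loops); each class
root substitutes a fixed fraction of non-signature sites within the same
hydropathy category (per-class deterministic RNG) and implants its
signature residues, so paralog families are genuinely homologous — as real
subfamilies are — and reference-anchored mapping operates in a realistic
identity regime.  Family variants then substitute non-signature sites
uniformly over the 19 alternatives at the requested divergence; signature
sites are frozen and no indels are introduced by default, so
anchored-mapping tests isolate column bookkeeping from gap handling.

The fill alphabets exclude Asn and Cys, so the only NPA motifs and the
only mercury-candidate Cys in a root are the implanted ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .assays import SwellingTimecourse, UptakeMeasurement, VW_WATER, \
    MOSM_TO_MOL_PER_CM3
from .io import GeneModel, ProteinRecord

AMINO20 = "ACDEFGHIKLMNPQRSTVWY"
TM_FILL = "ILVFMA"  # strongly hydrophobic, no N/C
LOOP_FILL = "GSTDEKQRHP"  # hydrophilic, no N/C

#: Seed of the shared ancestral fill all class roots descend from.
ANCESTOR_SEED = 7_102_003
#: Fraction of non-signature sites a class root substitutes (within the
#: same hydropathy category) relative to the ancestor.  Kept moderate so
#: cross-class global alignments stay in the reliable-identity regime.
CLASS_DIVERGENCE = 0.25


@dataclass(frozen=True)
class SequenceLayout:
    """Coordinate plan shared by all class roots (0-based positions)."""

    length: int = 263
    tm_blocks: tuple[tuple[int, int], ...] = (
        (8, 30), (48, 70), (94, 116), (128, 150), (162, 184), (214, 236),
    )
    npa_b: int = 75   # Asn of the loop-B box (1-based 76)
    npa_e: int = 191  # Asn of the loop-E box (1-based 192)
    tetrad: tuple[int, int, int, int] = (55, 179, 188, 194)  # 1-based 56/180/189/195
    froger: tuple[int, int, int, int, int] = (120, 198, 200, 240, 244)

    def signature_sites(self) -> frozenset[int]:
        sites = set(self.tetrad) | set(self.froger)
        sites |= {self.npa_b, self.npa_b + 1, self.npa_b + 2}
        sites |= {self.npa_e, self.npa_e + 1, self.npa_e + 2}
        return frozenset(sites)


@dataclass(frozen=True)
class ClassSpec:
    """Signature definition of one subfamily used by the generator."""

    label: str
    npa_b_triplet: str
    npa_e_triplet: str
    tetrad: tuple[str, str, str, str]
    froger: tuple[str, str, str, str, str]
    layout: SequenceLayout = field(default_factory=SequenceLayout)

    def __post_init__(self) -> None:
        import re

        for trip in (self.npa_b_triplet, self.npa_e_triplet):
            if not re.fullmatch(r"N[PA][APSTV]", trip):
                raise ValueError(f"triplet {trip!r} does not match N-[PA]-[APSTV]")
        for res in self.tetrad + self.froger:
            if res not in AMINO20:
                raise ValueError(f"invalid signature residue {res!r}")
        if not 255 <= self.layout.length <= 320:
            raise ValueError("layout length must lie within 255-320 residues")


#: Built-in class specs mirroring the four vertebrate subfamilies, plus the
#: NPA-variant forms observed within them (NAA, NPP, NPS, NPV, NPT boxes).
BUILTIN_SPECS: dict[str, ClassSpec] = {
    "water-selective": ClassSpec(
        "water-selective", "NPA", "NPA",
        tetrad=("F", "H", "C", "R"), froger=("T", "S", "A", "Y", "W"),
    ),
    "glp": ClassSpec(
        "glp", "NPA", "NPA",
        tetrad=("W", "G", "F", "R"), froger=("Y", "D", "K", "P", "L"),
    ),
    "aqp8-like": ClassSpec(
        "aqp8-like", "NPA", "NPA",
        tetrad=("H", "I", "C", "R"), froger=("T", "S", "A", "Y", "W"),
    ),
    "unorthodox": ClassSpec(
        "unorthodox", "NPA", "NPT",
        tetrad=("S", "L", "G", "Q"), froger=("G", "S", "E", "Y", "W"),
    ),
    # NPA-variant forms of the above classes.
    "glp-aqp7-like": ClassSpec(
        "glp", "NAA", "NPT",
        tetrad=("W", "G", "Y", "R"), froger=("Y", "D", "K", "P", "L"),
    ),
    "aqp8ab-like": ClassSpec(
        "aqp8-like", "NPP", "NPA",
        tetrad=("H", "V", "C", "R"), froger=("T", "S", "A", "Y", "W"),
    ),
    "aqp8b-like": ClassSpec(
        "aqp8-like", "NPS", "NPV",
        tetrad=("H", "I", "C", "R"), froger=("T", "S", "A", "Y", "W"),
    ),
}


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one generated artifact, keyed by its id."""

    id: str
    kind: str  # "sequence" | "gene" | "swelling" | "uptake"
    truth: dict
    seed: int


# ---------------------------------------------------------------------------
# Sequence families
# ---------------------------------------------------------------------------

def _ancestral_fill(layout: SequenceLayout) -> tuple[np.ndarray, np.ndarray]:
    """Shared ancestor sequence and its TM mask (deterministic)."""
    rng = np.random.default_rng(ANCESTOR_SEED)
    seq = np.empty(layout.length, dtype="<U1")
    tm_mask = np.zeros(layout.length, dtype=bool)
    for s, e in layout.tm_blocks:
        tm_mask[s:e] = True
    tm_fill = np.array(list(TM_FILL))
    loop_fill = np.array(list(LOOP_FILL))
    seq[tm_mask] = tm_fill[rng.integers(0, len(tm_fill), tm_mask.sum())]
    seq[~tm_mask] = loop_fill[rng.integers(0, len(loop_fill), (~tm_mask).sum())]
    return seq, tm_mask


def build_root(spec: ClassSpec) -> ProteinRecord:
    """Deterministic class root.

    Starts from the shared ancestral fill, substitutes ``CLASS_DIVERGENCE``
    of the non-signature sites within the same hydropathy category
    (per-class RNG keyed on the label), then implants the class signatures.
    """
    layout = spec.layout
    rng = np.random.default_rng(zlib.crc32(spec.label.encode()) & 0x7FFFFFFF)
    seq, tm_mask = _ancestral_fill(layout)
    sig = layout.signature_sites()
    tm_fill = list(TM_FILL)
    loop_fill = list(LOOP_FILL)
    for i in range(layout.length):
        if i in sig or rng.random() >= CLASS_DIVERGENCE:
            continue
        pool = [a for a in (tm_fill if tm_mask[i] else loop_fill) if a != seq[i]]
        seq[i] = pool[rng.integers(0, len(pool))]
    for pos, res in zip(layout.tetrad, spec.tetrad):
        seq[pos] = res
    for pos, res in zip(layout.froger, spec.froger):
        seq[pos] = res
    seq[layout.npa_b:layout.npa_b + 3] = list(spec.npa_b_triplet)
    seq[layout.npa_e:layout.npa_e + 3] = list(spec.npa_e_triplet)
    return ProteinRecord(
        id=f"{spec.label}_root",
        residues="".join(seq),
        description=f"synthetic {spec.label} class root",
    )


def generate_family(
    spec: ClassSpec, n: int, divergence: float, seed: int
) -> tuple[list[ProteinRecord], list[SimulationTruth]]:
    """Generate ``n`` variants of a class root at the given divergence.

    ``divergence`` is the expected proportion of substituted non-signature
    sites; signature sites are frozen so every variant keeps the implanted
    NPA boxes, ar/R tetrad and P1-P5 residues at their layout positions.
    """
    if not 0.0 <= divergence <= 0.6:
        raise ValueError("divergence must lie in [0, 0.6]")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    root = np.array(list(build_root(spec).residues))
    mutable = np.array(
        [i not in spec.layout.signature_sites() for i in range(len(root))]
    )
    records, truths = [], []
    alphabet = np.array(list(AMINO20))
    for k in range(n):
        seq = root.copy()
        hit = mutable & (rng.random(len(root)) < divergence)
        for i in np.flatnonzero(hit):
            choices = alphabet[alphabet != seq[i]]
            seq[i] = choices[rng.integers(0, len(choices))]
        rid = f"{spec.label}_{k:03d}"
        records.append(ProteinRecord(
            rid, "".join(seq), f"synthetic {spec.label} variant"
        ))
        truths.append(SimulationTruth(
            id=rid, kind="sequence",
            truth={"true_class": spec.label, "divergence": divergence},
            seed=seed,
        ))
    return records, truths


# ---------------------------------------------------------------------------
# Gene models and hybrids
# ---------------------------------------------------------------------------

def _split_peptides(residues: str, n_exons: int) -> list[str]:
    """Split a protein into near-equal contiguous exon peptides."""
    bounds = np.linspace(0, len(residues), n_exons + 1).astype(int)
    return [residues[bounds[i]:bounds[i + 1]] for i in range(n_exons)]


def _gene_model(gene_id: str, peptides: list[str], chromosome: str,
                intron_length: int, offset: int = 1000) -> GeneModel:
    exons = []
    pos = offset
    for pep in peptides:
        exons.append((pos, pos + 3 * len(pep)))
        pos += 3 * len(pep) + intron_length
    return GeneModel(gene_id, chromosome, "+", tuple(exons))


def generate_gene(
    spec: ClassSpec, n_exons: int = 4, divergence: float = 0.15,
    seed: int = 0, gene_id: str | None = None, intron_length: int = 500,
) -> tuple[GeneModel, list[str], SimulationTruth]:
    """A non-hybrid gene: one family variant split into coding exons."""
    records, _ = generate_family(spec, 1, divergence, seed)
    peptides = _split_peptides(records[0].residues, n_exons)
    gid = gene_id or f"{spec.label}_gene_{seed}"
    model = _gene_model(gid, peptides, "chrSim", intron_length)
    truth = SimulationTruth(gid, "gene",
                            {"hybrid": False, "true_class": spec.label}, seed)
    return model, peptides, truth


def generate_hybrid_gene(
    spec_a: ClassSpec, spec_b: ClassSpec, breakpoint_exon: int,
    exon_layout: list[int] | None = None, seed: int = 0,
    gene_id: str = "hybrid_gene", intron_length: int = 500,
) -> tuple[GeneModel, list[str], SimulationTruth]:
    """A chimeric gene: exons up to ``breakpoint_exon`` from family A's root,
    the remainder from family B's root.

    ``exon_layout`` lists per-exon peptide lengths (default: eight near-equal
    exons).  ``breakpoint_exon`` counts the A-derived exons and must leave at
    least one exon on each side.
    """
    n_exons = len(exon_layout) if exon_layout else 8
    if not 0 < breakpoint_exon < n_exons:
        raise ValueError("breakpoint must leave >=1 exon on each side")
    root_a = build_root(spec_a).residues
    root_b = build_root(spec_b).residues
    if exon_layout:
        bounds = np.concatenate([[0], np.cumsum(exon_layout)])
        pep_a = [root_a[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
        pep_b = [root_b[bounds[i]:bounds[i + 1]] for i in range(n_exons)]
    else:
        pep_a = _split_peptides(root_a, n_exons)
        pep_b = _split_peptides(root_b, n_exons)
    peptides = pep_a[:breakpoint_exon] + pep_b[breakpoint_exon:]
    model = _gene_model(gene_id, peptides, "chrSim", intron_length)
    truth = SimulationTruth(
        gene_id, "gene",
        {
            "hybrid": spec_a.label != spec_b.label,
            "family_a": spec_a.label, "family_b": spec_b.label,
            "breakpoint_exon": breakpoint_exon,
        },
        seed,
    )
    return model, peptides, truth


# ---------------------------------------------------------------------------
# Swelling time-courses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OocyteGeometry:
    """Spherical oocyte geometry (typical Xenopus oocyte, ~1.2 mm across)."""

    diameter_cm: float = 0.12

    @property
    def v0(self) -> float:
        return np.pi * self.diameter_cm ** 3 / 6.0

    @property
    def surface(self) -> float:
        return np.pi * self.diameter_cm ** 2


def simulate_swelling(
    true_pf: float,
    geometry: OocyteGeometry = OocyteGeometry(),
    osm_in: float = 200.0,
    osm_out: float = 20.0,
    n_points: int = 11,
    dt: float = 2.0,
    noise_sd: float = 0.005,
    seed: int = 0,
    oocyte_id: str = "oo1",
    group: str = "construct",
) -> tuple[SwellingTimecourse, SimulationTruth]:
    """Forward-simulate the initial linear swelling phase for a known Pf.

    V/V0(t) = 1 + [Pf * S * Vw * (Osm_in - Osm_out) / V0] * t + eps(t) with
    i.i.d. normal noise.  Defaults mimic the standard assay: transfer from
    200 to 20 mOsm medium and imaging every 2 s over the first 20 s.
    """
    if n_points < 3:
        raise ValueError("need >=3 time points")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_points) * dt
    gradient = (osm_in - osm_out) * MOSM_TO_MOL_PER_CM3
    slope = true_pf * geometry.surface * VW_WATER * gradient / geometry.v0
    v = 1.0 + slope * t + rng.normal(0.0, noise_sd, n_points)
    tc = SwellingTimecourse(
        oocyte_id=oocyte_id, group=group,
        times=tuple(float(x) for x in t),
        relative_volume=tuple(float(x) for x in v),
        osm_in=osm_in, osm_out=osm_out,
        diameter_cm=geometry.diameter_cm,
    )
    truth = SimulationTruth(
        oocyte_id, "swelling",
        {"true_pf": true_pf, "slope": float(slope), "noise_sd": noise_sd},
        seed,
    )
    return tc, truth


# ---------------------------------------------------------------------------
# Solute uptake counts
# ---------------------------------------------------------------------------

def _overdispersed_counts(rng, mean: float, dispersion: float, size: int):
    """Negative-binomial counts with variance = dispersion * mean."""
    if mean <= 0:
        raise ValueError("count means must be positive")
    if dispersion <= 1.0:
        return rng.poisson(mean, size).astype(float)
    p = 1.0 / dispersion
    r = mean * p / (1.0 - p)
    return rng.negative_binomial(r, p, size).astype(float)


def simulate_uptake(
    true_rate_ratio: float,
    control_mean: float = 150.0,
    baseline_mean: float = 30.0,
    n_per_group: int = 10,
    dispersion: float = 1.5,
    seed: int = 0,
    solute: str = "glycerol",
    groups: tuple[str, str] = ("construct", "water"),
) -> tuple[list[UptakeMeasurement], list[SimulationTruth]]:
    """Simulate a two-group uptake assay with a known rate ratio.

    Counts are baseline + true-signal draws from an over-dispersed
    (negative-binomial) count model; the recorded zero-time baseline is an
    independent draw of the same baseline process, mirroring the separate
    zero-time measurement used for external-binding subtraction.  Defaults
    follow the standard design of 10 oocytes per group.
    """
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    if true_rate_ratio <= 0:
        raise ValueError("rate ratio must be positive")
    rng = np.random.default_rng(seed)
    expressing, control = groups
    out: list[UptakeMeasurement] = []
    truths: list[SimulationTruth] = []
    for group, mean in ((expressing, control_mean * true_rate_ratio),
                        (control, control_mean)):
        signal = _overdispersed_counts(rng, mean, dispersion, n_per_group)
        bound = _overdispersed_counts(rng, baseline_mean, dispersion, n_per_group)
        baseline = _overdispersed_counts(rng, baseline_mean, dispersion,
                                         n_per_group)
        for i in range(n_per_group):
            oid = f"{group}_{solute}_{i:02d}"
            out.append(UptakeMeasurement(
                oocyte_id=oid, group=group, solute=solute,
                counts=float(signal[i] + bound[i]),
                baseline_counts=float(baseline[i]),
            ))
            truths.append(SimulationTruth(
                oid, "uptake",
                {"true_mean": mean, "true_rate_ratio": true_rate_ratio},
                seed,
            ))
    return out, truths


# ---------------------------------------------------------------------------
# Reference fixtures
# ---------------------------------------------------------------------------

def reference_fixture_records() -> dict[str, ProteinRecord]:
    """The two synthetic reference frames used for anchored mapping.

    The aquaporin frame carries the classical water-channel signature
    (F/H/C/R tetrad at 1-based 56/180/189/195); the Glp frame carries the
    glycerol-facilitator signature.  Both are generator roots, so the
    packaged reference FASTA can be regenerated byte-identically.
    """
    aqp = replace(build_root(BUILTIN_SPECS["water-selective"]),
                  id="synthAQP1_ref",
                  description="synthetic water-selective reference frame")
    glp = replace(build_root(BUILTIN_SPECS["glp"]),
                  id="synthGLP_ref",
                  description="synthetic glycerol-facilitator reference frame")
    return {"aquaporin": aqp, "glp": glp}
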