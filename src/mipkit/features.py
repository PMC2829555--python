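"""Structural feature extraction for MIP-superfamily proteins.

For each protein this module derives the features that drive subfamily
classification:

* transmembrane (TM) segments from Kyte-Doolittle hydropathy,
* the two Asn-Pro-Ala (NPA) boxes on loops B and E, including the variant
  third positions seen across the family (pattern ``N-[PA]-[APSTV]``),
* the aromatic/arginine (ar/R) constriction tetrad, located by mapping
  annotated anchor positions from a reference channel through a global
  pairwise alignment,
* the five Froger discriminant residues (P1-P5) that separate
  water-selective channels from glycerol facilitators, and
* a flag for a potentially mercury-sensitive Cys shortly upstream of the
  loop-E NPA box.

TM prediction is a deliberate offline stand-in for server-based predictors:
maximal unions of hydropathy windows above a cutoff, merged across short
gaps.  It is tunable (window/threshold/merge/min-span) and externally
produced TM annotations can be supplied instead via a TSV.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io import ProteinRecord, ValidationError, read_fasta

NPA_PATTERN = re.compile(r"(?=(N[PA][APSTV]))")

AROMATIC = frozenset("FYW")

FROGER_POSITIONS = ("P1", "P2", "P3", "P4", "P5")

#: Anchor names expected in a reference annotation.
ARR_ANCHORS = ("arR_aromatic", "arR_histidine", "arR_cysteine", "arR_arginine")
NPA_ANCHORS = ("npa_b", "npa_e")


# ---------------------------------------------------------------------------
# Alignment parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignParams:
    """Pairwise alignment settings used throughout the pipeline.

    Defaults (BLOSUM62, gap open 10, extend 0.5, end gaps penalised) follow
    common practice for full-length homolog alignment and are stated here so
    every identity and anchored mapping in the pipeline is reproducible.
    """

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    mode: str = "global"

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = self.mode
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_ALIGN = AlignParams()


# ---------------------------------------------------------------------------
# Feature data types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMSegment:
    start: int
    end: int
    mean_hydropathy: float

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class NpaBox:
    """One NPA box: 0-based Asn position, observed triplet, loop label."""

    asn_position: int
    triplet: str
    loop: str  # "B" or "E"

    def __post_init__(self) -> None:
        if not NPA_PATTERN.match(self.triplet + " "):
            raise ValidationError(f"triplet {self.triplet!r} is not N-[PA]-[APSTV]")


@dataclass(frozen=True)
class AnchorHit:
    """Query coordinate of one mapped reference anchor (or missing)."""

    name: str
    query_position: int | None  # 0-based; None when the query gaps the column
    residue: str | None


@dataclass(frozen=True)
class ArRTetrad:
    """The four ar/R constriction slots, in sequence order."""

    aromatic: AnchorHit
    histidine_site: AnchorHit
    cysteine_site: AnchorHit
    arginine_site: AnchorHit

    def slots(self) -> tuple[AnchorHit, ...]:
        return (self.aromatic, self.histidine_site,
                self.cysteine_site, self.arginine_site)

    def residues(self) -> tuple[str | None, ...]:
        return tuple(s.residue for s in self.slots())


@dataclass(frozen=True)
class FrogerTable:
    """Editable P1-P5 discriminant residue sets.

    ``aquaporin[pos]`` / ``glp[pos]`` hold the residues considered
    characteristic of water-selective channels and of glycerol facilitators
    at each discriminant position.  The packaged default encodes the
    consensus sets as reproduced across the aquaporin literature and is
    version-stamped into every profile so edited tables remain auditable.
    """

    aquaporin: dict[str, frozenset[str]]
    glp: dict[str, frozenset[str]]
    version: str

    @classmethod
    def load(cls, path=None) -> "FrogerTable":
        if path is None:
            ref = resources.files("mipkit.data") / "froger_discriminants.tsv"
            with resources.as_file(ref) as p:
                return cls.load(p)
        aq: dict[str, frozenset[str]] = {}
        gl: dict[str, frozenset[str]] = {}
        version = "unversioned"
        with open(path) as fh:
            for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"
            ):
                if row["position"] == "__version__":
                    version = row["aquaporin_allowed"]
                    continue
                aq[row["position"]] = frozenset(row["aquaporin_allowed"])
                gl[row["position"]] = frozenset(row["glp_allowed"])
        missing = set(FROGER_POSITIONS) - set(aq)
        if missing:
            raise ValidationError(f"discriminant table lacks {sorted(missing)}")
        return cls(aq, gl, version)


@dataclass(frozen=True)
class FrogerProfile:
    """Residues observed at P1-P5 plus per-set match flags and counts."""

    residues: dict[str, str | None]
    aquaporin_matches: dict[str, bool]
    glp_matches: dict[str, bool]
    table_version: str

    @property
    def aquaporin_count(self) -> int:
        return sum(self.aquaporin_matches.values())

    @property
    def glp_count(self) -> int:
        return sum(self.glp_matches.values())


@dataclass(frozen=True)
class MipFeatureProfile:
    record_id: str
    tm_segments: tuple[TMSegment, ...]
    npa_boxes: tuple[NpaBox, ...]
    tetrad: ArRTetrad | None
    froger: FrogerProfile | None
    mercury_cys_flag: bool
    frame: str | None  # "aquaporin" or "glp" reference frame used
    frame_ambiguous: bool
    non_mip: bool
    alignment_score: float | None

    def to_dict(self) -> dict:
        return {
            "record_id": self.record_id,
            "tm_segments": [[s.start, s.end, round(s.mean_hydropathy, 3)]
                            for s in self.tm_segments],
            "npa_boxes": [[b.loop, b.asn_position, b.triplet]
                          for b in self.npa_boxes],
            "tetrad": None if self.tetrad is None else
                      [[h.name, h.query_position, h.residue]
                       for h in self.tetrad.slots()],
            "froger": None if self.froger is None else {
                "residues": self.froger.residues,
                "aquaporin_count": self.froger.aquaporin_count,
                "glp_count": self.froger.glp_count,
                "table_version": self.froger.table_version,
            },
            "mercury_cys_flag": self.mercury_cys_flag,
            "frame": self.frame,
            "frame_ambiguous": self.frame_ambiguous,
            "non_mip": self.non_mip,
            "alignment_score": self.alignment_score,
        }


# ---------------------------------------------------------------------------
# TM segment prediction
# ---------------------------------------------------------------------------

def predict_tm_segments(
    record: ProteinRecord,
    window: int = 19,
    threshold: float = 1.6,
    merge_gap: int = 3,
    min_span: int = 15,
) -> list[TMSegment]:
    """Predict TM segments from window-averaged Kyte-Doolittle hydropathy.

    The window mean is assigned to the centre residue; maximal runs of
    centres at or above ``threshold`` are found, runs separated by fewer
    than ``merge_gap`` residues are merged, each run is expanded by half a
    window on both sides (clipped at the midpoint where expansions of
    neighbouring runs would overlap), and segments shorter than
    ``min_span`` are dropped.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be a positive odd integer")
    n = len(record.residues)
    if n < window:
        raise ValueError(
            f"{record.id}: sequence length {n} shorter than window {window}"
        )
    half = window // 2
    scores = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in record.residues])
    kernel = np.ones(window) / window
    win_means = np.convolve(scores, kernel, mode="valid")
    centers = np.flatnonzero(win_means >= threshold) + half
    if centers.size == 0:
        return []
    runs: list[list[int]] = []  # [first_center, last_center]
    for c in centers:
        if runs and c - runs[-1][1] <= merge_gap:
            runs[-1][1] = int(c)
        else:
            runs.append([int(c), int(c)])
    extents = [[max(0, a - half), min(n, b + half + 1)] for a, b in runs]
    for prev, cur in zip(extents, extents[1:]):  # clip overlaps at midpoint
        if cur[0] < prev[1]:
            mid = (cur[0] + prev[1]) // 2
            prev[1], cur[0] = mid, mid
    return [
        TMSegment(s, e, float(scores[s:e].mean()))
        for s, e in extents
        if e - s >= min_span
    ]


def read_tm_annotations(path) -> dict[str, list[TMSegment]]:
    """Ingest externally predicted TM segments (TSV: id, start, end)."""
    out: dict[str, list[TMSegment]] = {}
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.setdefault(row["id"], []).append(
                TMSegment(int(row["start"]), int(row["end"]), float("nan"))
            )
    return out


# ---------------------------------------------------------------------------
# NPA boxes
# ---------------------------------------------------------------------------

def scan_npa_candidates(residues: str) -> list[tuple[int, str]]:
    """All (position, triplet) matches of N-[PA]-[APSTV], overlapping included."""
    return [(m.start(), m.group(1)) for m in NPA_PATTERN.finditer(residues)]


def find_npa_boxes(
    record: ProteinRecord,
    b_center: int | None = None,
    e_center: int | None = None,
    window: int = 15,
) -> list[NpaBox]:
    """Locate the loop-B and loop-E NPA boxes.

    Without positional hints the first two motif matches are labelled B and
    E.  When expected centres are given (reference-mapped NPA positions or
    TM-derived loop midpoints), the candidate closest to each centre within
    ``window`` residues is chosen; ties go to the leftmost candidate.
    Returns 0-2 boxes; an empty list marks a sequence with no NPA motif.
    """
    cands = scan_npa_candidates(record.residues)
    if not cands:
        return []
    chosen: list[NpaBox] = []
    used: set[int] = set()
    if b_center is not None or e_center is not None:
        for loop, center in (("B", b_center), ("E", e_center)):
            if center is None:
                continue
            in_win = [
                (abs(pos - center), pos, trip)
                for pos, trip in cands
                if pos not in used and abs(pos - center) <= window
            ]
            if in_win:
                _, pos, trip = min(in_win)
                chosen.append(NpaBox(pos, trip, loop))
                used.add(pos)
        if chosen:
            return sorted(chosen, key=lambda b: b.asn_position)
    for (pos, trip), loop in zip(cands[:2], ("B", "E")):
        chosen.append(NpaBox(pos, trip, loop))
    if len(chosen) == 1:
        chosen[0] = NpaBox(chosen[0].asn_position, chosen[0].triplet, "B")
    return chosen


# ---------------------------------------------------------------------------
# Anchored position mapping
# ---------------------------------------------------------------------------

def anchor_positions(
    query: ProteinRecord,
    reference: ProteinRecord,
    anchors: list[int],
    params: AlignParams = DEFAULT_ALIGN,
    names: list[str] | None = None,
) -> list[AnchorHit]:
    """Map 1-based reference positions onto the query via global alignment.

    Each anchor column of the pairwise alignment yields the aligned query
    residue, or a missing marker when the query has a gap in that column.
    Mapped positions are strictly increasing across anchors.
    """
    for a in anchors:
        if not 1 <= a <= len(reference):
            raise ValueError(
                f"anchor {a} outside reference {reference.id} "
                f"(length {len(reference)})"
            )
    names = names or [f"anchor_{a}" for a in anchors]
    aln = params.make_aligner().align(reference.residues, query.residues)[0]
    idx = aln.indices  # shape (2, ncols); -1 where a sequence gaps
    ref_to_col = {int(r): c for c, r in enumerate(idx[0]) if r >= 0}
    hits: list[AnchorHit] = []
    for name, a in zip(names, anchors):
        col = ref_to_col[a - 1]
        q = int(idx[1][col])
        if q < 0:
            hits.append(AnchorHit(name, None, None))
        else:
            hits.append(AnchorHit(name, q, query.residues[q]))
    return hits


# ---------------------------------------------------------------------------
# Reference set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceFrame:
    record: ProteinRecord
    anchors: dict[str, int]  # anchor name -> 1-based reference position


@dataclass(frozen=True)
class ReferenceSet:
    """An aquaporin-frame and a Glp-frame reference with annotated anchors."""

    aquaporin: ReferenceFrame
    glp: ReferenceFrame

    @classmethod
    def load(cls, fasta_path=None, anchors_path=None) -> "ReferenceSet":
        """Load the packaged (synthetic) references or a user-supplied pair."""
        if fasta_path is None:
            data = resources.files("mipkit.data")
            with resources.as_file(data / "references.fasta") as fp, \
                 resources.as_file(data / "reference_anchors.tsv") as ap:
                return cls.load(fp, ap)
        records = {r.id: r for r in read_fasta(fasta_path)}
        anchors: dict[str, dict[str, int]] = {}
        with open(anchors_path) as fh:
            for row in csv.DictReader(
                (l for l in fh if not l.startswith("#")), delimiter="\t"
            ):
                anchors.setdefault(row["reference_id"], {})[row["anchor_name"]] = \
                    int(row["position"])
        frames: dict[str, ReferenceFrame] = {}
        for rid, rec in records.items():
            frame = "aquaporin" if "aqp" in rid.lower() else "glp"
            frames[frame] = ReferenceFrame(rec, anchors[rid])
        return cls(frames["aquaporin"], frames["glp"])


# ---------------------------------------------------------------------------
# Profile assembly
# ---------------------------------------------------------------------------

def extract_feature_profile(
    record: ProteinRecord,
    references: ReferenceSet | None = None,
    froger_table: FrogerTable | None = None,
    params: AlignParams = DEFAULT_ALIGN,
    mercury_window: int = 15,
    frame_margin: float = 5.0,
    score_floor: float = 50.0,
    tm_kwargs: dict | None = None,
) -> MipFeatureProfile:
    """Assemble the full feature profile of one sequence.

    The query is globally aligned against both reference frames.  Each
    frame's anchor mapping is corroborated against the motif scan (an NPA
    anchor should land exactly on a scanned N-[PA]-[APSTV] Asn); the
    mapping with more corroborated NPA anchors wins, ties falling to the
    better alignment score.  A score margin below ``frame_margin`` marks
    the profile frame-ambiguous.  A sequence with no NPA motif and a best
    score below ``score_floor`` is flagged non-MIP.  The mercury flag is
    set when a Cys occurs within ``mercury_window`` residues upstream of
    the loop-E NPA Asn.
    """
    references = references or ReferenceSet.load()
    froger_table = froger_table or FrogerTable.load()
    aligner = params.make_aligner()
    score_aqp = aligner.score(references.aquaporin.record.residues,
                              record.residues)
    score_glp = aligner.score(references.glp.record.residues, record.residues)
    best = max(score_aqp, score_glp)
    ambiguous = abs(score_aqp - score_glp) < frame_margin

    candidates = scan_npa_candidates(record.residues)
    if not candidates and best < score_floor:
        return MipFeatureProfile(
            record_id=record.id, tm_segments=(), npa_boxes=(), tetrad=None,
            froger=None, mercury_cys_flag=False, frame=None,
            frame_ambiguous=False, non_mip=True, alignment_score=float(best),
        )

    anchor_names = list(ARR_ANCHORS) + list(FROGER_POSITIONS) + list(NPA_ANCHORS)
    motif_positions = {pos for pos, _ in candidates}
    mappings = []
    for frame_name, score in (("aquaporin", score_aqp), ("glp", score_glp)):
        frame = getattr(references, frame_name)
        anchor_pos = [frame.anchors[n] for n in anchor_names]
        hits = anchor_positions(record, frame.record, anchor_pos, params,
                                names=anchor_names)
        named = {h.name: h for h in hits}
        corroborated = sum(
            named[n].query_position in motif_positions for n in NPA_ANCHORS
        )
        mappings.append((corroborated, score, frame_name, named))
    mappings.sort(key=lambda m: (m[0], m[1]), reverse=True)
    _, _, frame_name, by_name = mappings[0]
    frame = getattr(references, frame_name)

    # Register rectification: when both NPA anchors land on scanned motifs
    # with one consistent offset, the query is colinear with the reference
    # around both pore landmarks, and every anchor is snapped to that
    # register.  Inconsistent or uncorroborated offsets (real indels) fall
    # back to pure alignment-column mapping.
    qb = by_name["npa_b"].query_position
    qe = by_name["npa_e"].query_position
    if qb in motif_positions and qe in motif_positions:
        off_b = qb - (frame.anchors["npa_b"] - 1)
        off_e = qe - (frame.anchors["npa_e"] - 1)
        if off_b == off_e:
            snapped = {}
            for n in anchor_names:
                p = frame.anchors[n] - 1 + off_b
                if 0 <= p < len(record.residues):
                    snapped[n] = AnchorHit(n, p, record.residues[p])
                else:
                    snapped[n] = AnchorHit(n, None, None)
            by_name = snapped

    tetrad = ArRTetrad(*(by_name[n] for n in ARR_ANCHORS))
    residues = {p: by_name[p].residue for p in FROGER_POSITIONS}
    froger = FrogerProfile(
        residues=residues,
        aquaporin_matches={
            p: residues[p] is not None and residues[p] in froger_table.aquaporin[p]
            for p in FROGER_POSITIONS
        },
        glp_matches={
            p: residues[p] is not None and residues[p] in froger_table.glp[p]
            for p in FROGER_POSITIONS
        },
        table_version=froger_table.version,
    )

    boxes = tuple(find_npa_boxes(
        record,
        b_center=by_name["npa_b"].query_position,
        e_center=by_name["npa_e"].query_position,
    ))
    mercury = False
    for box in boxes:
        if box.loop == "E":
            lo = max(0, box.asn_position - mercury_window)
            mercury = "C" in record.residues[lo:box.asn_position]

    tm = tuple(predict_tm_segments(record, **(tm_kwargs or {})))
    return MipFeatureProfile(
        record_id=record.id, tm_segments=tm, npa_boxes=boxes, tetrad=tetrad,
        froger=froger, mercury_cys_flag=mercury, frame=frame_name,
        frame_ambiguous=ambiguous, non_mip=False, alignment_score=float(best),
    )
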