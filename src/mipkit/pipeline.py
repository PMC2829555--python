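"""End-to-end pipeline stages driven by a declarative configuration.

Each runner reads its inputs, executes one stage of the analysis and writes
plain-text outputs (TSV with a ``#`` parameter header, JSON-lines profiles,
newick trees) plus a run manifest (config echo, constants, package version,
seed) sufficient to reproduce every output byte-identically.  Stages are
independent: the assay runner needs no sequence input and vice versa.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assays import (
    VW_WATER,
    compute_pf,
    group_compare,
    read_swelling_csv,
    read_uptake_csv,
    uptake_summary,
)
from .classify import (
    classify_subfamily,
    concordance_table,
    predict_substrate,
)
from .features import (
    AlignParams,
    FrogerTable,
    ReferenceSet,
    extract_feature_profile,
)
from .io import read_fasta
from .phylo import identity_matrix, nj_tree, to_distance, tree_to_newick
from .simulate import (
    BUILTIN_SPECS,
    generate_family,
    simulate_swelling,
    simulate_uptake,
)

logger = logging.getLogger("mipkit")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are echoed into the manifest."""

    fasta: str | None = None
    reference_fasta: str | None = None  # packaged synthetic refs when None
    reference_anchors: str | None = None
    froger_table: str | None = None
    swelling_csv: str | None = None
    uptake_csv: str | None = None
    predictions_tsv: str | None = None
    measured_tsv: str | None = None
    out_dir: str = "mipkit_out"
    seed: int = 1
    identity_mode: str = "gapped-global"
    distance_correction: str = "p-distance"
    align: AlignParams = field(default_factory=AlignParams)
    alpha: float = 0.01
    vw: float = VW_WATER
    fit_window: tuple[float, float] = (0.0, 20.0)
    control_group: str = "water"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        align = AlignParams(**raw.pop("align", {}))
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "fit_window" in raw:
            raw["fit_window"] = tuple(raw["fit_window"])
        return cls(align=align, **raw)

    def validate_paths(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config field {name!r} is required for this stage")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")


def _write_manifest(config: PipelineConfig, out_dir: Path, stage: str,
                    extra: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "mipkit_version": __version__,
        "seed": config.seed,
        "constants": {"vw_cm3_per_mol": config.vw,
                      "mosm_to_mol_per_cm3": 1e-6},
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    if extra:
        manifest.update(extra)
    with open(out_dir / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def _tsv_header(params: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in params.items())


def _load_refs(config: PipelineConfig):
    refs = ReferenceSet.load(config.reference_fasta, config.reference_anchors) \
        if config.reference_fasta else ReferenceSet.load()
    table = FrogerTable.load(config.froger_table)
    return refs, table


def run_classify(config: PipelineConfig) -> Path:
    """Feature extraction + subfamily calls + substrate predictions."""
    config.validate_paths("fasta")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.fasta)
    if not records:
        raise ValueError(f"{config.fasta}: no sequences to classify")
    refs, table = _load_refs(config)
    rows = []
    with open(out_dir / "profiles.jsonl", "w") as fh:
        for rec in records:
            profile = extract_feature_profile(rec, refs, table, config.align)
            fh.write(json.dumps(profile.to_dict()) + "\n")
            call = classify_subfamily(profile)
            row = {
                "id": rec.id,
                "subfamily": call.label,
                "score": round(call.score, 3),
                "evidence": ";".join(call.evidence),
                "non_mip": profile.non_mip,
                "mercury_cys": profile.mercury_cys_flag,
            }
            if call.label != "unclassified":
                pred = predict_substrate(call)
                row["predicted_permeants"] = "+".join(sorted(pred.permeants)) or "none"
                row["qualifier"] = pred.qualifier
            else:
                row["predicted_permeants"] = ""
                row["qualifier"] = ""
            rows.append(row)
    calls = pd.DataFrame(rows).set_index("id")
    path = out_dir / "subfamily_calls.tsv"
    with open(path, "w") as fh:
        fh.write(_tsv_header({"align": config.align,
                              "froger_table": table.version}))
        calls.to_csv(fh, sep="\t")
    counts = calls["subfamily"].value_counts()
    if (calls["subfamily"] == "unclassified").all():
        logger.warning("no input sequence was classifiable as a MIP")
    summary = out_dir / "class_counts.tsv"
    counts.rename("count").to_csv(summary, sep="\t")
    _write_manifest(config, out_dir, "classify",
                    {"n_sequences": len(records)})
    return path


def run_phylo(config: PipelineConfig) -> Path:
    """Identity/similarity matrices and (for >=3 sequences) an NJ tree."""
    config.validate_paths("fasta")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_fasta(config.fasta)
    if len(records) < 2:
        raise ValueError("phylo stage needs >=2 sequences")
    ident, simil = identity_matrix(records, config.identity_mode, config.align)
    for name, mat in (("identity", ident), ("similarity", simil)):
        with open(out_dir / f"{name}_matrix.tsv", "w") as fh:
            fh.write(_tsv_header({"mode": config.identity_mode,
                                  "align": config.align}))
            mat.round(2).to_csv(fh, sep="\t")
    if len(records) >= 3:
        tree = nj_tree(to_distance(ident, config.distance_correction))
        (out_dir / "nj_tree.nwk").write_text(tree_to_newick(tree) + "\n")
    else:
        logger.warning("fewer than 3 sequences; NJ tree skipped")
    _write_manifest(config, out_dir, "phylo", {"n_sequences": len(records)})
    return out_dir / "identity_matrix.tsv"


def run_assays(config: PipelineConfig) -> Path:
    """Pf table, uptake table and (when predictions exist) concordance."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wrote = []
    measured_sets: dict[str, set[str]] = {}
    if config.swelling_csv:
        config.validate_paths("swelling_csv")
        courses = read_swelling_csv(config.swelling_csv)
        groups = sorted({tc.group for tc in courses})
        if config.control_group not in groups:
            raise ValueError(
                f"swelling data lacks the control group "
                f"{config.control_group!r} (groups: {groups})"
            )
        per_oocyte = pd.DataFrame([
            {"oocyte_id": tc.oocyte_id, "group": tc.group,
             "pf_cm_per_s": compute_pf(tc, config.vw, config.fit_window).pf}
            for tc in courses
        ])
        control_pf = per_oocyte.loc[
            per_oocyte.group == config.control_group, "pf_cm_per_s"]
        rows = []
        for group, sub in per_oocyte.groupby("group"):
            row = {
                "group": group, "n": len(sub),
                "pf_mean": sub.pf_cm_per_s.mean(),
                "pf_sem": sub.pf_cm_per_s.sem(),
            }
            if group != config.control_group:
                cmp_res = group_compare(sub.pf_cm_per_s, control_pf,
                                        alpha=config.alpha)
                row.update(fold_change=cmp_res.fold_change,
                           p_value=cmp_res.p_value,
                           significant=cmp_res.significant)
                if cmp_res.significant:
                    measured_sets.setdefault(group, set()).add("water")
                else:
                    measured_sets.setdefault(group, set())
            rows.append(row)
        path = out_dir / "pf_table.tsv"
        with open(path, "w") as fh:
            fh.write(_tsv_header({"vw": config.vw,
                                  "fit_window_s": config.fit_window,
                                  "alpha": config.alpha,
                                  "control": config.control_group}))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
        wrote.append(path)
    if config.uptake_csv:
        config.validate_paths("uptake_csv")
        measurements = read_uptake_csv(config.uptake_csv)
        summary = uptake_summary(measurements, config.control_group,
                                 config.alpha)
        table = summary.table.copy()
        table["p_value_vs_control"] = [
            summary.comparisons[(g, s)].p_value
            if (g, s) in summary.comparisons else float("nan")
            for g, s in zip(table.group, table.solute)
        ]
        table["significant"] = table.p_value_vs_control < config.alpha
        for (group, solute), cmp_res in summary.comparisons.items():
            measured_sets.setdefault(group, set())
            if cmp_res.significant:
                measured_sets[group].add(solute)
        path = out_dir / "uptake_table.tsv"
        with open(path, "w") as fh:
            fh.write(_tsv_header({"alpha": config.alpha,
                                  "control": config.control_group}))
            table.to_csv(fh, sep="\t", index=False)
        wrote.append(path)
    if not wrote:
        raise ValueError("assay stage needs swelling_csv and/or uptake_csv")
    if config.predictions_tsv:
        config.validate_paths("predictions_tsv")
        preds_raw = pd.read_csv(config.predictions_tsv, sep="\t",
                                comment="#", index_col=0)
        from .classify import SubstratePrediction

        predictions = {
            str(i): SubstratePrediction(
                frozenset(p.split("+")) - {"none", ""}, "predicted")
            for i, p in preds_raw["predicted_permeants"].items()
            if isinstance(p, str)
        }
        if config.measured_tsv:
            config.validate_paths("measured_tsv")
            meas_raw = pd.read_csv(config.measured_tsv, sep="\t", index_col=0)
            measured = {
                str(i): {s for s in ("water", "glycerol", "urea")
                         if int(row[s]) == 1}
                for i, row in meas_raw.iterrows()
            }
        else:
            measured = measured_sets
        overlap = set(predictions) & set(measured)
        if overlap:
            conc = concordance_table(predictions,
                                     {k: measured[k] for k in overlap})
            path = out_dir / "concordance.tsv"
            with open(path, "w") as fh:
                fh.write(_tsv_header(
                    {"agreement": round(conc.agreement, 4)}))
                conc.table.to_csv(fh, sep="\t")
            wrote.append(path)
    _write_manifest(config, out_dir, "assays")
    return wrote[0]


def run_simulate(config: PipelineConfig, n_per_class: int = 10,
                 divergence: float = 0.15) -> Path:
    """Emit a complete synthetic input bundle (FASTA, CSVs, truth TSV)."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_fasta

    records, truths = [], []
    for i, name in enumerate(
            ("water-selective", "glp", "aqp8-like", "unorthodox")):
        recs, tr = generate_family(BUILTIN_SPECS[name], n_per_class,
                                   divergence, seed=config.seed + i)
        records += recs
        truths += tr
    write_fasta(records, out_dir / "sequences.fasta")

    swell_rows = []
    for g, (group, pf) in enumerate((("construct", 0.015), ("water", 0.0015))):
        for i in range(10):
            tc, tr = simulate_swelling(
                pf, seed=config.seed * 1000 + g * 100 + i,
                oocyte_id=f"{group}_{i:02d}", group=group)
            truths.append(tr)
            for t, v in zip(tc.times, tc.relative_volume):
                swell_rows.append({
                    "oocyte_id": tc.oocyte_id, "group": tc.group,
                    "time_s": t, "rel_volume": v, "osm_in": tc.osm_in,
                    "osm_out": tc.osm_out, "diameter_cm": tc.diameter_cm,
                })
    pd.DataFrame(swell_rows).to_csv(out_dir / "swelling.csv", index=False)

    ups, tr = simulate_uptake(5.0, seed=config.seed + 77)
    truths += tr
    pd.DataFrame([{
        "oocyte_id": m.oocyte_id, "group": m.group, "solute": m.solute,
        "counts": m.counts, "baseline_counts": m.baseline_counts,
    } for m in ups]).to_csv(out_dir / "uptake.csv", index=False)

    pd.DataFrame([{
        "id": t.id, "kind": t.kind, "seed": t.seed,
        **{f"truth_{k}": v for k, v in t.truth.items()},
    } for t in truths]).to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    _write_manifest(config, out_dir, "simulate",
                    {"n_per_class": n_per_class, "divergence": divergence})
    return out_dir / "sequences.fasta"
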