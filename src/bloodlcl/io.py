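"""Stable CSV schemas for every table the pipeline reads or writes.

Plain CSV is the interchange format; instrument-proprietary exports are out
of scope. Every writer prepends a single comment line ``# bloodlcl.<table>.v1``
naming and versioning the schema, which the readers ignore via pandas'
comment handling, so each table round-trips through its own reader without
loss. Sentinels: a missing TCRbeta melting peak is written as an empty field
and read back as None; imputed Cts carry explicit boolean flags.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import AssayPanel, OriginCall, ThresholdConfig
from .clock import MethylationProfile
from .qpcr import AmplificationCurve, MeltCurve
from .synthetic import CohortConfig, CohortSample, Dist, SampleTruth

SCHEMAS = {
    "curves": "# bloodlcl.curves.v1: sample_id,assay,x_kind,x,fluorescence",
    "truth": ("# bloodlcl.truth.v1: sample_id,tissue,diploid_genomes_per_reaction,"
              "ebv_copies_per_genome,t_cell_fraction,chronological_age,passage_effect"),
    "methylation": ("# bloodlcl.methylation.v1: sample_id,elovl2_cpg5,klf14_cpg2,"
                    "trim59_cpg5,chronological_age,tissue"),
    "panels": ("# bloodlcl.panels.v1: sample_id,ct_gapdh,ct_ebv,ct_tcrg,"
               "tcrb_max_tm,ebv_imputed,tcrg_imputed"),
    "calls": ("# bloodlcl.calls.v1: sample_id,ebv_ratio,tcrg_ratio,tcrb_max_tm,"
              "label_ebv,label_tcrg,label_tcrb,combined,votes_blood,votes_lcl"),
}


def _write_table(df: pd.DataFrame, path, schema: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMAS[schema] + "\n")
        # %.17g is round-trip exact for float64, so every table re-reads losslessly
        df.to_csv(fh, index=False, float_format="%.17g")


def _read_table(path) -> pd.DataFrame:
    # round_trip parsing pairs with the %.17g writer for lossless floats
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# -- curves -----------------------------------------------------------------

def curves_to_frame(amplification: list[AmplificationCurve],
                    melts: list[MeltCurve]) -> pd.DataFrame:
    rows = []
    for c in amplification:
        rows.append(pd.DataFrame({
            "sample_id": c.sample_id, "assay": c.assay, "x_kind": "cycle",
            "x": c.cycles, "fluorescence": c.fluorescence}))
    for m in melts:
        rows.append(pd.DataFrame({
            "sample_id": m.sample_id, "assay": m.assay, "x_kind": "temperature_C",
            "x": m.temperatures, "fluorescence": m.fluorescence}))
    if not rows:
        return pd.DataFrame(columns=["sample_id", "assay", "x_kind", "x", "fluorescence"])
    return pd.concat(rows, ignore_index=True)


def write_curves(path, amplification: list[AmplificationCurve],
                 melts: list[MeltCurve]) -> None:
    _write_table(curves_to_frame(amplification, melts), path, "curves")


def read_curves(path) -> tuple[list[AmplificationCurve], list[MeltCurve]]:
    df = _read_table(path)
    amps: list[AmplificationCurve] = []
    melts: list[MeltCurve] = []
    for (sid, assay, kind), grp in df.groupby(["sample_id", "assay", "x_kind"], sort=True):
        grp = grp.sort_values("x")
        if kind == "cycle":
            amps.append(AmplificationCurve(str(sid), str(assay),
                                           grp["x"].to_numpy(),
                                           grp["fluorescence"].to_numpy()))
        elif kind == "temperature_C":
            melts.append(MeltCurve(str(sid), str(assay),
                                   grp["x"].to_numpy(),
                                   grp["fluorescence"].to_numpy()))
        else:
            raise ValueError(f"unknown x_kind {kind!r} in curve table")
    return amps, melts


# -- sample truth -----------------------------------------------------------

def write_truth(path, truths: list[SampleTruth]) -> None:
    df = pd.DataFrame([dataclasses.asdict(t) for t in truths],
                      columns=["sample_id", "tissue", "diploid_genomes_per_reaction",
                               "ebv_copies_per_genome", "t_cell_fraction",
                               "chronological_age", "passage_effect"])
    _write_table(df, path, "truth")


def read_truth(path) -> list[SampleTruth]:
    df = _read_table(path)
    return [SampleTruth(**{k: (str(v) if k in ("sample_id", "tissue") else float(v))
                           for k, v in row.items()})
            for row in df.to_dict("records")]


def load_truth_annotations(path) -> pd.DataFrame:
    """Read a truth or annotation table down to (sample_id, tissue).

    Accepts the generator's truth schema or any CSV with ``sample_id`` and
    ``tissue`` columns; tissue values are blood, LCL or unknown.
    """
    df = _read_table(path)
    if "sample_id" not in df.columns or "tissue" not in df.columns:
        raise ValueError("annotation table needs 'sample_id' and 'tissue' columns")
    out = df[["sample_id", "tissue"]].copy()
    out["sample_id"] = out["sample_id"].astype(str)
    out["tissue"] = out["tissue"].astype(str)
    bad = set(out["tissue"]) - {"blood", "LCL", "unknown"}
    if bad:
        raise ValueError(f"unknown tissue annotation(s): {sorted(bad)}")
    return out


# -- methylation ------------------------------------------------------------

def write_methylation(path, profiles: list[MethylationProfile]) -> None:
    df = pd.DataFrame([dataclasses.asdict(p) for p in profiles],
                      columns=["sample_id", "elovl2_cpg5", "klf14_cpg2",
                               "trim59_cpg5", "chronological_age", "tissue"])
    _write_table(df, path, "methylation")


def read_methylation(path) -> list[MethylationProfile]:
    df = _read_table(path)
    return [MethylationProfile(
        sample_id=str(r["sample_id"]), elovl2_cpg5=float(r["elovl2_cpg5"]),
        klf14_cpg2=float(r["klf14_cpg2"]), trim59_cpg5=float(r["trim59_cpg5"]),
        chronological_age=float(r["chronological_age"]), tissue=str(r["tissue"]))
        for r in df.to_dict("records")]


# -- assay panels -----------------------------------------------------------

def write_panels(path, panels: list[AssayPanel]) -> None:
    df = pd.DataFrame([dataclasses.asdict(p) for p in panels],
                      columns=["sample_id", "ct_gapdh", "ct_ebv", "ct_tcrg",
                               "tcrb_max_tm", "ebv_imputed", "tcrg_imputed"])
    _write_table(df, path, "panels")


def read_panels(path) -> list[AssayPanel]:
    df = _read_table(path)
    panels = []
    for r in df.to_dict("records"):
        tm = r["tcrb_max_tm"]
        panels.append(AssayPanel(
            sample_id=str(r["sample_id"]), ct_gapdh=float(r["ct_gapdh"]),
            ct_ebv=float(r["ct_ebv"]), ct_tcrg=float(r["ct_tcrg"]),
            tcrb_max_tm=None if pd.isna(tm) else float(tm),
            ebv_imputed=bool(r["ebv_imputed"]), tcrg_imputed=bool(r["tcrg_imputed"])))
    return panels


# -- origin calls -----------------------------------------------------------

def write_calls(path, calls: list[OriginCall]) -> None:
    df = pd.DataFrame([dataclasses.asdict(c) for c in calls],
                      columns=["sample_id", "ebv_ratio", "tcrg_ratio", "tcrb_max_tm",
                               "label_ebv", "label_tcrg", "label_tcrb",
                               "combined", "votes_blood", "votes_lcl"])
    _write_table(df, path, "calls")


def read_calls(path) -> list[OriginCall]:
    df = _read_table(path)
    calls = []
    for r in df.to_dict("records"):
        tm = r["tcrb_max_tm"]
        calls.append(OriginCall(
            sample_id=str(r["sample_id"]), ebv_ratio=float(r["ebv_ratio"]),
            tcrg_ratio=float(r["tcrg_ratio"]),
            tcrb_max_tm=None if pd.isna(tm) else float(tm),
            label_ebv=str(r["label_ebv"]), label_tcrg=str(r["label_tcrg"]),
            label_tcrb=str(r["label_tcrb"]), combined=str(r["combined"]),
            votes_blood=int(r["votes_blood"]), votes_lcl=int(r["votes_lcl"])))
    return calls


# -- cohort convenience -----------------------------------------------------

def write_cohort(out_dir, samples: list[CohortSample]) -> dict[str, Path]:
    """Write a generated cohort's curve, truth and methylation tables."""
    out_dir = Path(out_dir)
    paths = {
        "curves": out_dir / "curves.csv",
        "truth": out_dir / "truth.csv",
        "methylation": out_dir / "methylation.csv",
    }
    amps = [c for s in samples for c in s.amplification.values()]
    melts = [s.melt for s in samples]
    write_curves(paths["curves"], amps, melts)
    write_truth(paths["truth"], [s.truth for s in samples])
    write_methylation(paths["methylation"], [s.methylation for s in samples])
    return paths


# -- configuration ----------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, Dist):
        return {"kind": obj.kind, "a": obj.a, "b": obj.b}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_resolved_config(path, **sections) -> None:
    """Serialize the resolved configuration next to the outputs it produced."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {name: _jsonable(cfg) for name, cfg in sections.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def _dist_from_obj(obj) -> Dist:
    if isinstance(obj, dict):
        return Dist(kind=str(obj["kind"]), a=float(obj["a"]), b=float(obj.get("b", 0.0)))
    if isinstance(obj, (list, tuple)):
        return Dist(str(obj[0]), float(obj[1]), float(obj[2]) if len(obj) > 2 else 0.0)
    raise ValueError(f"cannot interpret distribution spec {obj!r}")


def cohort_config_from_dict(d: dict) -> CohortConfig:
    """Build a CohortConfig from a parsed YAML/JSON mapping.

    Unknown keys raise, naming the offending field.
    """
    dist_fields = {f.name for f in dataclasses.fields(CohortConfig)
                   if "Dist" in str(f.type)}
    valid = {f.name for f in dataclasses.fields(CohortConfig)}
    kwargs = {}
    for key, value in d.items():
        if key not in valid:
            raise ValueError(f"unknown cohort configuration field {key!r}")
        kwargs[key] = _dist_from_obj(value) if key in dist_fields else value
    return CohortConfig(**kwargs)


def threshold_config_from_dict(d: dict) -> ThresholdConfig:
    valid = {f.name for f in dataclasses.fields(ThresholdConfig)}
    bad = set(d) - valid
    if bad:
        raise ValueError(f"unknown threshold configuration field(s): {sorted(bad)}")
    return ThresholdConfig(**d)


def load_config_file(path) -> dict:
    """Load a YAML (or JSON) pipeline configuration file."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    out = yaml.safe_load(text)
    return {} if out is None else out
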