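"""Readers and writers for the plain-text formats of the pipeline.

Formats:
  * events CSV — header ``event,I1,I2,I3``, one row per cell;
  * summary TSV — one row per sample with medians, ratio, efficiency, flags;
  * calibration JSON — ``{S1, S2, alpha, slope, intercept, r_squared, n_samples}``;
  * titration CSV — ``concentration_nM,response``;
  * kinetics CSV — ``time_min,ratio`` plus events CSV ``time_min,kind,concentration_nM``;
  * library map TSV — ``barcode  gene  insertion_location  intergenic``;
  * sample sheet CSV — ``sample_id,fastq,role,cycle,replicate,biosensor``;
  * counts / enrichment / report TSV — genes in rows.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import KineticsTrace, Titration
from .cytofret import (
    BleedthroughFactors,
    EventTable,
    FretEfficiency,
    ChannelSummary,
    SpectralCalibration,
)
from .sortseq import CountTable, LibraryMap


def read_events_csv(path: str | Path, sample_id: str | None = None) -> EventTable:
    df = pd.read_csv(path)
    missing = {"I1", "I2", "I3"} - set(df.columns)
    if missing:
        raise ValueError(f"events CSV {path} lacks columns {sorted(missing)}")
    return EventTable(
        sample_id=sample_id or Path(path).stem,
        events=df[["I1", "I2", "I3"]].to_numpy(dtype=float),
    )


def write_events_csv(table: EventTable, path: str | Path) -> None:
    df = pd.DataFrame(table.events, columns=["I1", "I2", "I3"])
    df.insert(0, "event", np.arange(len(df)))
    df.to_csv(path, index=False)


def write_summary_tsv(
    rows: list[tuple[ChannelSummary, float, FretEfficiency]], path: str | Path
) -> None:
    """One row per sample: (summary, fret_ratio, efficiency) triples."""
    records = [
        {
            "sample_id": s.sample_id,
            "n_events": s.n_events,
            "m1": s.m1,
            "m2": s.m2,
            "m3": s.m3,
            "fret_ratio": ratio,
            "E_percent": eff.E,
            "flags": ";".join(sorted(eff.flags)),
        }
        for s, ratio, eff in rows
    ]
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)


def write_calibration_json(calib: SpectralCalibration, path: str | Path) -> None:
    payload = {
        "S1": calib.factors.S1,
        "S2": calib.factors.S2,
        "alpha": calib.alpha,
        "slope": calib.slope,
        "intercept": calib.intercept,
        "r_squared": calib.r_squared,
        "n_samples": calib.n_samples,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_calibration_json(path: str | Path) -> SpectralCalibration:
    d = json.loads(Path(path).read_text())
    return SpectralCalibration(
        factors=BleedthroughFactors(S1=d["S1"], S2=d["S2"]),
        alpha=d["alpha"],
        slope=d["slope"],
        intercept=d["intercept"],
        n_samples=d["n_samples"],
        r_squared=d["r_squared"],
    )


def read_titration_csv(path: str | Path, response_kind: str = "efficiency") -> Titration:
    df = pd.read_csv(path)
    return Titration(
        concentration=df["concentration_nM"].to_numpy(float),
        response=df["response"].to_numpy(float),
        response_kind=response_kind,
    )


def write_titration_csv(data: Titration, path: str | Path) -> None:
    pd.DataFrame(
        {"concentration_nM": data.concentration, "response": data.response}
    ).to_csv(path, index=False)


def read_kinetics_csv(
    trace_path: str | Path, events_path: str | Path | None = None
) -> KineticsTrace:
    df = pd.read_csv(trace_path)
    events: tuple = ()
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = tuple(
            (float(r["time_min"]), str(r["kind"]), float(r["concentration_nM"]))
            for _, r in ev.iterrows()
        )
    return KineticsTrace(
        time=df["time_min"].to_numpy(float),
        ratio=df["ratio"].to_numpy(float),
        events=events,
    )


def write_kinetics_csv(
    trace: KineticsTrace, trace_path: str | Path, events_path: str | Path | None = None
) -> None:
    pd.DataFrame({"time_min": trace.time, "ratio": trace.ratio}).to_csv(
        trace_path, index=False
    )
    if events_path is not None:
        pd.DataFrame(
            trace.events, columns=["time_min", "kind", "concentration_nM"]
        ).to_csv(events_path, index=False)


def read_library_map(path: str | Path) -> LibraryMap:
    df = pd.read_csv(path, sep="\t", dtype={"barcode": str, "gene": str})
    return LibraryMap(records=df)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "role", "cycle", "replicate", "biosensor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet lacks columns {sorted(missing)}")
    return df


def write_counts_tsv(table: CountTable, path: str | Path) -> None:
    table.counts.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path, samples: pd.DataFrame) -> CountTable:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    return CountTable(counts=counts, samples=samples.set_index("sample_id"))
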