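"""Semiquantitative AP-MS interaction scoring.

For every protein group in a bait-vs-control co-immunoprecipitation
experiment two descriptive scores are computed:

* **abundance** — mean MS signal intensity over the bait replicates
  divided by the protein's molecular mass (intensity units per kDa);
* **specificity** — ratio of mean bait intensity to mean negative-control
  intensity, with the background level arbitrarily set to 1 intensity
  unit for proteins not detected in the control purification.

These are the axes of the abundance-vs-specificity scatter used to read
out interactors; no statistical enrichment model is layered on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import TagkitError

#: Default column resolution for MaxQuant-style proteinGroups tables.
DEFAULT_COLUMN_MAP = {
    "group_id": ["group_id", "id", "Protein group IDs"],
    "protein_ids": ["protein_ids", "Protein IDs", "Majority protein IDs"],
    "mol_weight_kda": ["mol_weight_kda", "Mol. weight [kDa]", "mol_weight"],
}


@dataclass
class ProteinGroupTable:
    """Per-protein-group intensities across bait replicates and control
    runs. Missing intensities are recorded as 0."""

    data: pd.DataFrame
    bait_runs: list[str]
    control_runs: list[str]

    def __post_init__(self) -> None:
        if not self.bait_runs or not self.control_runs:
            raise TagkitError("need at least one bait replicate and one control run")
        for col in ("group_id", "mol_weight_kda", *self.bait_runs, *self.control_runs):
            if col not in self.data.columns:
                raise TagkitError(f"table lacks required column {col!r}")
        runs = self.bait_runs + self.control_runs
        self.data = self.data.copy()
        self.data[runs] = self.data[runs].fillna(0.0).astype(float)
        if (self.data[runs].to_numpy() < 0).any():
            raise TagkitError("intensities must be >= 0")
        if (self.data["mol_weight_kda"] <= 0).any():
            raise TagkitError("molecular weights must be positive (kDa)")

    @classmethod
    def from_tsv(
        cls,
        path,
        bait_runs: Iterable[str],
        control_runs: Iterable[str],
        column_map: dict | None = None,
    ) -> "ProteinGroupTable":
        """Read a proteinGroups-style TSV. Run labels resolve either to a
        column of the same name or to ``Intensity <label>``."""
        raw = pd.read_csv(path, sep="\t")
        cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}

        def resolve(key):
            for cand in cmap[key]:
                if cand in raw.columns:
                    return cand
            raise TagkitError(f"cannot resolve column for {key!r} in {list(raw.columns)[:8]}...")

        def resolve_run(label):
            for cand in (label, f"Intensity {label}"):
                if cand in raw.columns:
                    return cand
            raise TagkitError(f"cannot resolve intensity column for run {label!r}")

        bait_runs, control_runs = list(bait_runs), list(control_runs)
        frame = pd.DataFrame(
            {
                "group_id": raw[resolve("group_id")].astype(str),
                "protein_ids": (
                    raw[resolve("protein_ids")].astype(str)
                    if any(c in raw.columns for c in cmap["protein_ids"])
                    else raw[resolve("group_id")].astype(str)
                ),
                "mol_weight_kda": raw[resolve("mol_weight_kda")].astype(float),
            }
        )
        for label in bait_runs + control_runs:
            frame[label] = raw[resolve_run(label)].astype(float)
        return cls(frame, bait_runs, control_runs)


@dataclass(frozen=True)
class CoipScore:
    group_id: str
    abundance: float
    specificity: float
    detected_in_control: bool


def compute_abundance(row, bait_runs: Iterable[str]) -> float:
    """Mean bait-replicate intensity (missing = 0) per kDa."""
    mw = float(row["mol_weight_kda"])
    if mw <= 0:
        raise TagkitError("molecular weight must be positive")
    intensities = [float(row[r]) for r in bait_runs]
    if not intensities:
        raise TagkitError("need at least one bait replicate")
    return float(np.mean(intensities)) / mw


def compute_specificity(
    row,
    bait_runs: Iterable[str],
    control_runs: Iterable[str],
    background_floor: float = 1.0,
) -> float:
    """Mean bait intensity over mean control intensity; the background
    floor replaces the denominator when the protein is undetected in
    every control run."""
    bait_mean = float(np.mean([float(row[r]) for r in bait_runs]))
    control_mean = float(np.mean([float(row[r]) for r in control_runs]))
    denom = control_mean if control_mean > 0 else background_floor
    return bait_mean / denom


def score_table(
    table: ProteinGroupTable,
    background_floor: float = 1.0,
    out_tsv=None,
) -> pd.DataFrame:
    """One score per group, sorted by descending specificity then
    abundance. When ``out_tsv`` is given, a plot-ready file with log10
    axes is written alongside the raw scores."""
    rows = []
    for _, row in table.data.iterrows():
        rows.append(
            CoipScore(
                group_id=str(row["group_id"]),
                abundance=compute_abundance(row, table.bait_runs),
                specificity=compute_specificity(
                    row, table.bait_runs, table.control_runs, background_floor
                ),
                detected_in_control=any(float(row[r]) > 0 for r in table.control_runs),
            )
        )
    scores = pd.DataFrame([s.__dict__ for s in rows])
    scores = scores.sort_values(
        ["specificity", "abundance", "group_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    if out_tsv is not None:
        out = scores.copy()
        with np.errstate(divide="ignore"):
            out["log10_abundance"] = np.where(
                out["abundance"] > 0, np.log10(out["abundance"]), np.nan
            )
            out["log10_specificity"] = np.where(
                out["specificity"] > 0, np.log10(out["specificity"]), np.nan
            )
        out.to_csv(out_tsv, sep="\t", index=False)
    return scores


def score_records(table: ProteinGroupTable, background_floor: float = 1.0) -> list[CoipScore]:
    df = score_table(table, background_floor)
    return [CoipScore(**rec) for rec in df.to_dict("records")]
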