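"""Lesion-extent arithmetic from printed volume measurements.

Lesion extent is expressed as a percentage of a reference volume, with two
measurement modes:

``remaining``
    The measured volume is tissue that survived; percent lesioned is
    100 * (1 - measured / reference).  Used for histological remaining-
    volume measurements against atlas volumes.
``lesioned``
    The measured volume is the lesion itself (e.g. T2-weighted hypersignal);
    percent lesioned is 100 * measured / reference.

Reported percentages are rounded half-away-from-zero to 2 decimals to match
tabular reporting conventions; full precision is retained internally.
Summary tables report mean volumes truncated to integers and mean percents
as the mean of the per-subject rounded percents (the convention that
reproduces the bundled demonstration tables).
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass

import pandas as pd

MODES = ("remaining", "lesioned")


def _round2(x: float) -> float:
    """Round half away from zero to 2 decimals."""
    return math.floor(abs(x) * 100 + 0.5) / 100 * (1 if x >= 0 else -1)


@dataclass
class LesionRecord:
    subject_id: str
    side: str  # "left" | "right" | "total"
    mode: str
    measured_volume: float
    reference_volume: float

    @property
    def percent(self) -> float:
        return lesion_percent(self.measured_volume, self.reference_volume,
                              self.mode)


def lesion_percent(measured: float, reference: float, mode: str,
                   *, _rounded: bool = True) -> float:
    """Percent of the reference structure lesioned.

    With ``mode="remaining"`` a measured volume exceeding the reference
    would give a negative percentage; a warning is issued and the value is
    clamped to 0.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; one of {MODES}")
    if reference <= 0:
        raise ValueError("reference volume must be positive")
    if measured < 0:
        raise ValueError("measured volume must be non-negative")
    if mode == "remaining":
        pct = 100.0 * (1.0 - measured / reference)
        if pct < 0:
            warnings.warn(
                f"remaining volume {measured} exceeds reference {reference}; "
                "percent clamped to 0")
            pct = 0.0
    else:
        pct = 100.0 * measured / reference
        if pct > 100.0:
            warnings.warn("lesion volume exceeds reference; clamped to 100%")
            pct = 100.0
    return _round2(pct) if _rounded else pct


def lesion_table_summary(records: list[LesionRecord]) -> pd.DataFrame:
    """Per-subject and mean lesion extents, one column block per side.

    Returns a table with one row per subject plus a ``Mean`` row.  The mean
    volume is the truncated (floor) mean of the per-subject volumes; the
    mean percent is the mean of the per-subject 2-dp percents, rounded to
    2 dp.  Reference volumes must agree across subjects within each
    (side, mode) column when the mode is ``remaining`` (shared atlas
    reference); per-subject references are allowed for ``lesioned`` mode.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame(
        [{"subject": r.subject_id, "side": r.side, "mode": r.mode,
          "measured": r.measured_volume, "reference": r.reference_volume,
          "percent": r.percent} for r in records])
    for (side, mode), grp in df.groupby(["side", "mode"]):
        if mode == "remaining" and grp["reference"].nunique() > 1:
            raise ValueError(
                f"inconsistent reference volumes for side {side!r}")
    rows = []
    subjects = df["subject"].unique()
    sides = list(dict.fromkeys(df["side"]))
    for subj in subjects:
        row = {"subject": subj}
        for side in sides:
            rec = df[(df.subject == subj) & (df.side == side)]
            if len(rec):
                row[f"{side}_volume"] = float(rec.measured.iloc[0])
                row[f"{side}_percent"] = float(rec.percent.iloc[0])
        rows.append(row)
    mean_row = {"subject": "Mean"}
    for side in sides:
        sub = df[df.side == side]
        mean_row[f"{side}_volume"] = float(math.floor(sub.measured.mean()))
        mean_row[f"{side}_percent"] = _round2(float(sub.percent.mean()))
    rows.append(mean_row)
    return pd.DataFrame(rows).set_index("subject")


def _bundled(name: str) -> list[LesionRecord]:
    ref = importlib.resources.files("plastnet.data") / name
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t")
    return [LesionRecord(str(r.subject), r.side, r.mode,
                         float(r.measured), float(r.reference))
            for r in df.itertuples()]


def bundled_histology_records() -> list[LesionRecord]:
    """Demonstration dataset: histological remaining hippocampal volumes of
    five lesioned macaques against atlas volumes (remaining mode)."""
    return _bundled("histology_lesion_volumes.tsv")


def bundled_t2_records() -> list[LesionRecord]:
    """Demonstration dataset: T2-hypersignal lesion volumes of the same five
    macaques relative to whole-hippocampus volume (lesioned mode)."""
    return _bundled("t2_lesion_volumes.tsv")


def load_lesion_records(path) -> list[LesionRecord]:
    """Read a TSV ``subject, side, mode, measured, reference``."""
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "side", "mode", "measured", "reference"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lesion table missing columns: {sorted(missing)}")
    return [LesionRecord(str(r.subject), r.side, r.mode,
                         float(r.measured), float(r.reference))
            for r in df.itertuples()]
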