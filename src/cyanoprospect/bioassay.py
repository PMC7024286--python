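"""Antimicrobial growth-inhibition scoring from OD620 microplate readings.

Each extract x pathogen combination is read in replicate wells: S (bacterial
suspension plus test sample), T (suspension without sample) and B (sterile
medium). Percent growth inhibition per replicate is

    % inhibition = 100 - (OD_S - OD_B) / (OD_T - OD_B) * 100

Replicates are summarised as mean +/- SEM and an extract is called *active*
against a pathogen when the mean inhibition strictly exceeds the activity
threshold (50% by default). Values are deliberately not clipped to [0, 100]:
inhibition above 100 (OD_S below blank) or below 0 (growth stimulation) is
reported as-is and flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlateReading",
    "InhibitionResult",
    "ACTIVITY_THRESHOLD",
    "percent_inhibition",
    "summarize",
    "classify_active",
    "activity_table",
    "read_plate_csv",
    "write_plate_csv",
]

#: Mean % inhibition above which an extract is called active.
ACTIVITY_THRESHOLD = 50.0


@dataclass
class PlateReading:
    """Replicate OD620 wells for one extract against one pathogen.

    ``wells`` is a list of (od_sample, od_control, od_blank) triples, one per
    replicate; each replicate carries its own control and blank.
    """

    extract_id: str
    pathogen_id: str
    wells: list[tuple[float, float, float]]
    concentration: float = 100.0  # µg/mL

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("a plate reading needs at least one replicate")
        for rep, (s, t, b) in enumerate(self.wells, start=1):
            for name, od in (("sample", s), ("control", t), ("blank", b)):
                if not math.isfinite(od) or od < 0:
                    raise ValueError(
                        f"{self.extract_id}/{self.pathogen_id} replicate {rep}: "
                        f"{name} OD must be finite and >= 0, got {od}"
                    )


@dataclass
class InhibitionResult:
    extract_id: str
    pathogen_id: str
    mean_inhibition: float  # %
    sem: float  # %
    n: int
    active: bool
    concentration: float = 100.0
    out_of_range: bool = False  # any replicate outside [0, 100]
    single_replicate: bool = False


def percent_inhibition(odS: float, odT: float, odB: float) -> float:
    """Percent growth inhibition of one well against its control and blank.

    Requires odT > odB (the untreated control actually grew); raises otherwise.
    The result may exceed 100 or fall below 0 and is not clipped.
    """
    if odT <= odB:
        raise ValueError(
            f"failed growth control: OD_T ({odT}) must exceed OD_B ({odB})"
        )
    return 100.0 - (odS - odB) / (odT - odB) * 100.0


def summarize(reading: PlateReading, threshold: float = ACTIVITY_THRESHOLD) -> InhibitionResult:
    """Mean +/- SEM inhibition over replicates; SEM uses the n-1 sd over sqrt(n).

    Replicates whose growth control failed (OD_T <= OD_B) are excluded with a
    warning; if every replicate failed the whole reading is an error.
    """
    values = []
    for rep, (s, t, b) in enumerate(reading.wells, start=1):
        try:
            values.append(percent_inhibition(s, t, b))
        except ValueError:
            logger.warning(
                "%s/%s replicate %d excluded: control OD (%g) <= blank OD (%g)",
                reading.extract_id, reading.pathogen_id, rep, t, b,
            )
    if not values:
        raise ValueError(
            f"{reading.extract_id}/{reading.pathogen_id}: all replicate controls failed"
        )
    values = np.asarray(values)
    n = len(values)
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    result = InhibitionResult(
        extract_id=reading.extract_id,
        pathogen_id=reading.pathogen_id,
        mean_inhibition=mean,
        sem=sem,
        n=n,
        active=False,
        concentration=reading.concentration,
        out_of_range=bool(np.any((values < 0) | (values > 100))),
        single_replicate=(n == 1),
    )
    result.active = classify_active(result, threshold)
    return result


def classify_active(result: InhibitionResult, threshold: float = ACTIVITY_THRESHOLD) -> bool:
    """Active iff mean inhibition strictly exceeds the threshold (default 50%)."""
    return result.mean_inhibition > threshold


def activity_table(results, threshold: float = ACTIVITY_THRESHOLD) -> pd.DataFrame:
    """Activity report: extracts as rows, pathogens as columns.

    Active cells show "mean ± SEM" to two decimals; inactive cells show the
    "n.a." sentinel (not active at the tested concentration).
    """
    extracts = sorted({r.extract_id for r in results})
    pathogens = sorted({r.pathogen_id for r in results})
    table = pd.DataFrame("", index=extracts, columns=pathogens)
    table.index.name = "extract_id"
    for r in results:
        if classify_active(r, threshold):
            cell = f"{r.mean_inhibition:.2f} ± {r.sem:.2f}"
        else:
            cell = "n.a."
        table.at[r.extract_id, r.pathogen_id] = cell
    return table


def read_plate_csv(path) -> list[PlateReading]:
    """Read a long-format plate CSV.

    Expected columns: extract_id, pathogen_id, replicate, od_sample,
    od_control, od_blank, concentration_ug_ml.
    """
    frame = pd.read_csv(path)
    required = {"extract_id", "pathogen_id", "replicate", "od_sample",
                "od_control", "od_blank"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"plate CSV lacks columns: {sorted(missing)}")
    readings = []
    for (extract, pathogen), group in frame.groupby(
        ["extract_id", "pathogen_id"], sort=True
    ):
        group = group.sort_values("replicate")
        conc = float(group["concentration_ug_ml"].iloc[0]) \
            if "concentration_ug_ml" in group else 100.0
        wells = list(zip(group["od_sample"], group["od_control"], group["od_blank"]))
        readings.append(PlateReading(str(extract), str(pathogen), wells, conc))
    return readings


def write_plate_csv(readings, path) -> None:
    rows = []
    for r in readings:
        for rep, (s, t, b) in enumerate(r.wells, start=1):
            rows.append((r.extract_id, r.pathogen_id, rep, s, t, b, r.concentration))
    pd.DataFrame(
        rows,
        columns=["extract_id", "pathogen_id", "replicate", "od_sample",
                 "od_control", "od_blank", "concentration_ug_ml"],
    ).to_csv(path, index=False)
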