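"""Chemical shift perturbation analysis of an HSQC-monitored titration.

Peak lists recorded at increasing ligand:protein molar ratios are matched
across titration points, the combined 1H/15N shift change

    delta = sqrt(ddH^2 + ddN^2 / 25)

is computed per peak, and every peak is classified as vanished, broadened,
shifted or unperturbed.  The nitrogen changes are down-weighted by 1/5 both
in the combined shift and in the peak-matching metric, reflecting the ~5x
wider 15N shift dispersion.

Classification criteria (explicit, configurable):

* vanished   - present at the first point but absent (or below the noise
  floor) at the final point;
* broadened  - final/initial intensity ratio below ``broadening_ratio``
  (default 0.5) without vanishing;
* shifted    - final combined shift change above mean + k_sigma * SD of the
  non-vanished peaks (default k_sigma = 1);
* unperturbed - everything else.

Classes are assigned in that priority order and are mutually exclusive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

__all__ = [
    "PeakList",
    "PerturbationReport",
    "match_peaks",
    "compute_csp",
    "classify_peaks",
    "NITROGEN_SCALE",
    "DEFAULT_MATCH_TOLERANCE",
    "DEFAULT_BROADENING_RATIO",
    "DEFAULT_K_SIGMA",
]

NITROGEN_SCALE = 5.0
DEFAULT_MATCH_TOLERANCE = (0.05, 0.25)   # ppm (1H, 15N)
DEFAULT_BROADENING_RATIO = 0.5
DEFAULT_K_SIGMA = 1.0


@dataclass
class PeakList:
    """1H-15N peak positions and intensities at one titration point."""

    molar_ratio: float
    peaks: pd.DataFrame  # columns: id, dH_ppm, dN_ppm, intensity

    def __post_init__(self) -> None:
        required = {"id", "dH_ppm", "dN_ppm", "intensity"}
        if not required.issubset(self.peaks.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if self.peaks["id"].duplicated().any():
            raise ValueError("peak ids must be unique within a list")
        if not np.all(np.isfinite(self.peaks[["dH_ppm", "dN_ppm"]])):
            raise ValueError("peak positions must be finite")


@dataclass
class PerturbationReport:
    """Per-peak classes and final shift changes of one titration series."""

    classes: pd.DataFrame  # columns: id, class, csp_final, intensity_ratio
    shift_threshold: float
    noise_floor: float
    broadening_ratio: float
    k_sigma: float
    counts: dict[str, int] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = self.classes["class"].value_counts().to_dict()


def compute_csp(ddh: float | np.ndarray, ddn: float | np.ndarray) -> float | np.ndarray:
    """Combined shift change sqrt(ddH^2 + ddN^2/25), ppm."""
    return np.sqrt(np.square(ddh) + np.square(ddn) / NITROGEN_SCALE**2)


def match_peaks(
    reference: PeakList,
    other: PeakList,
    tolerances: tuple[float, float] = DEFAULT_MATCH_TOLERANCE,
) -> pd.DataFrame:
    """Greedy nearest-neighbour one-to-one pairing in scaled ppm space.

    Candidate pairs within the (1H, 15N) tolerance box are sorted by the
    scaled distance sqrt(dH^2 + (dN/5)^2) and accepted greedily, each peak
    used at most once.  Returns a table with columns ref_id, other_id
    (nullable) and distance; reference peaks without a partner are the
    candidates for "vanished".
    """
    tol_h, tol_n = tolerances
    if tol_h <= 0 or tol_n <= 0:
        raise ValueError("tolerances must be positive")
    ref = reference.peaks
    oth = other.peaks
    dh = ref["dH_ppm"].to_numpy()[:, None] - oth["dH_ppm"].to_numpy()[None, :]
    dn = ref["dN_ppm"].to_numpy()[:, None] - oth["dN_ppm"].to_numpy()[None, :]
    within = (np.abs(dh) <= tol_h) & (np.abs(dn) <= tol_n)
    dist = np.sqrt(dh**2 + (dn / NITROGEN_SCALE) ** 2)

    pairs = np.argwhere(within)
    order = np.argsort(dist[within], kind="stable")
    used_ref: set[int] = set()
    used_oth: set[int] = set()
    matches: dict[int, tuple[int, float]] = {}
    for i, j in pairs[order]:
        if i in used_ref or j in used_oth:
            continue
        used_ref.add(int(i))
        used_oth.add(int(j))
        matches[int(i)] = (int(j), float(dist[i, j]))

    rows = []
    for i, rid in enumerate(ref["id"]):
        if i in matches:
            j, d = matches[i]
            rows.append(dict(ref_id=rid, other_id=oth["id"].iloc[j], distance=d))
        else:
            rows.append(dict(ref_id=rid, other_id=pd.NA, distance=np.nan))
    return pd.DataFrame(rows)


def classify_peaks(
    series: list[PeakList],
    noise_floor: float,
    broadening_ratio: float = DEFAULT_BROADENING_RATIO,
    k_sigma: float = DEFAULT_K_SIGMA,
) -> PerturbationReport:
    """Classify every first-point peak from its trajectory across the series.

    Peaks are paired across titration points by their ids (the lists must
    use one consistent id scheme; an id present at a later point but not the
    first is an error).  The shifted threshold is mean + k_sigma * SD of the
    final combined shift changes, computed over non-vanished peaks.
    """
    if len(series) < 2:
        raise ValueError("need at least two titration points")
    first, last = series[0], series[-1]
    known = set(first.peaks["id"])
    for pl in series[1:]:
        extra = set(pl.peaks["id"]) - known
        if extra:
            raise ValueError(f"peak ids {sorted(extra)[:5]} absent from first point")

    f = first.peaks.set_index("id")
    l = last.peaks.set_index("id")

    rows = []
    for pid in f.index:
        i0 = float(f.loc[pid, "intensity"])
        if pid in l.index and float(l.loc[pid, "intensity"]) >= noise_floor:
            i1 = float(l.loc[pid, "intensity"])
            csp = float(
                compute_csp(
                    l.loc[pid, "dH_ppm"] - f.loc[pid, "dH_ppm"],
                    l.loc[pid, "dN_ppm"] - f.loc[pid, "dN_ppm"],
                )
            )
            vanished = False
        else:
            i1, csp, vanished = 0.0, np.nan, True
        rows.append(
            dict(
                id=pid,
                vanished=vanished,
                csp_final=csp,
                intensity_ratio=i1 / i0 if i0 != 0 else np.nan,
            )
        )
    df = pd.DataFrame(rows)

    surviving = df.loc[~df["vanished"], "csp_final"]
    threshold = float(surviving.mean() + k_sigma * surviving.std(ddof=0))

    def _label(row) -> str:
        if row["vanished"]:
            return "vanished"
        if row["intensity_ratio"] < broadening_ratio:
            return "broadened"
        if row["csp_final"] > threshold:
            return "shifted"
        return "unperturbed"

    df["class"] = df.apply(_label, axis=1)
    out = df[["id", "class", "csp_final", "intensity_ratio"]]
    return PerturbationReport(
        classes=out,
        shift_threshold=threshold,
        noise_floor=noise_floor,
        broadening_ratio=broadening_ratio,
        k_sigma=k_sigma,
    )


def read_peak_list(path, molar_ratio: float) -> PeakList:
    """Read a peak-list TSV with columns id, dH_ppm, dN_ppm, intensity."""
    return PeakList(molar_ratio, pd.read_csv(path, sep="\t"))


def write_peak_list(peaklist: PeakList, path) -> None:
    peaklist.peaks.to_csv(path, sep="\t", index=False, float_format="%.6g")
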