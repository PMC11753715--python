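"""Sex-linkage inference from normalized female/male sequencing depth.

A hemizygous X gives males half the read depth of females, so after
per-sample normalization the female/male depth ratio sits near 1 on
autosomes, near 2 on a fully degenerate X, and near 0 on the Y (females
carry no Y).  A young neo-X whose neo-Y partner retains a homology fraction
``theta`` attracts male depth proportional to (1 + theta)/2, placing its
ratio between the autosomal and X expectations.  This module computes
windowed median depths, normalized F/M ratio tables, per-scaffold linkage
calls under a configurable X threshold (default: inclusive >= 1.6), summary
statistics of neo-sex differentiation, and a least-squares single
changepoint locating the boundary between anc-X and neo-X segments.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .simdata import _natural_key

__all__ = [
    "FMRatioTable",
    "DifferentiationScore",
    "BreakpointEstimate",
    "make_windows",
    "window_medians",
    "fm_ratio",
    "classify_scaffolds",
    "differentiation_score",
    "detect_breakpoint",
]

LINKAGE_CLASSES = ("autosomal", "X_linked", "Y_linked", "ambiguous")


def make_windows(chrom_sizes: Mapping[str, int], window_size: int) -> pd.DataFrame:
    """Tile each chromosome with fixed windows; the last window may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    rows = []
    for chrom in sorted(chrom_sizes, key=_natural_key):
        size = int(chrom_sizes[chrom])
        if size <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length")
        for s in range(0, size, window_size):
            rows.append((chrom, s, min(s + window_size, size)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _interval_median(values: np.ndarray, lengths: np.ndarray) -> float:
    """Median of per-site depths given depth intervals expanded by length."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(lengths[order])
    total = int(cw[-1])
    lo, hi = (total - 1) // 2, total // 2
    i = int(np.searchsorted(cw, lo, side="right"))
    j = int(np.searchsorted(cw, hi, side="right"))
    return (float(v[i]) + float(v[j])) / 2.0


def window_medians(depth: pd.DataFrame, windows: pd.DataFrame) -> pd.DataFrame:
    """Median per-site depth of every window from a depth-interval stream.

    ``depth`` has columns chrom, start, end, depth (bedGraph-style,
    non-negative, non-overlapping per chromosome).  Intervals are expanded by
    length-weighting, so the result equals the median over individual sites.
    Windows without any covered site get depth 0 and ``empty=True``.
    """
    for col in ("chrom", "start", "end", "depth"):
        if col not in depth.columns:
            raise ValueError(f"depth stream missing column {col!r}")
    if (depth["depth"] < 0).any():
        raise ValueError("negative depth in input")
    if (depth["end"] <= depth["start"]).any():
        raise ValueError("depth interval with end <= start")
    known = set(windows["chrom"])
    unknown = sorted(set(depth["chrom"]) - known, key=_natural_key)
    if unknown:
        raise ValueError(f"depth intervals on chromosomes absent from tiling: {', '.join(unknown)}")

    out = windows.copy().reset_index(drop=True)
    out["depth"] = 0.0
    out["empty"] = True
    for chrom, d in depth.groupby("chrom", sort=False):
        d = d.sort_values(["start", "end"], kind="stable")
        starts = d["start"].to_numpy()
        ends = d["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            k = int(np.argmax(starts[1:] < ends[:-1]))
            raise ValueError(
                f"overlapping depth intervals on {chrom} near position {int(starts[k + 1])}"
            )
        vals = d["depth"].to_numpy(dtype=float)
        widx = out.index[out["chrom"] == chrom]
        for wi in widx:
            ws, we = int(out.at[wi, "start"]), int(out.at[wi, "end"])
            lo = int(np.searchsorted(ends, ws, side="right"))
            hi = int(np.searchsorted(starts, we, side="left"))
            if hi <= lo:
                continue
            clip_s = np.maximum(starts[lo:hi], ws)
            clip_e = np.minimum(ends[lo:hi], we)
            lengths = clip_e - clip_s
            keep = lengths > 0
            if not keep.any():
                continue
            out.at[wi, "depth"] = _interval_median(vals[lo:hi][keep], lengths[keep])
            out.at[wi, "empty"] = False
    return out


@dataclass
class FMRatioTable:
    """Per-window normalized female/male depth ratios and per-scaffold medians.

    ``windows`` carries norm_f, norm_m, ratio and log2_ratio per window;
    windows with raw male depth below the floor (candidate female-specific
    sequence) or without data are flagged and excluded from scaffold medians.
    """

    windows: pd.DataFrame
    scaffolds: pd.DataFrame
    norm_const_f: float
    norm_const_m: float
    normalization: str


def fm_ratio(
    cov_f: pd.DataFrame,
    cov_m: pd.DataFrame,
    normalization: str = "genome_median",
    min_m_depth: float = 2.0,
    autosome_chroms: list[str] | None = None,
) -> FMRatioTable:
    """Normalized female/male ratio per window and median ratio per scaffold.

    Each sample is divided by its own normalization constant: the genome-wide
    median window depth, or the median over ``autosome_chroms`` when
    ``normalization='autosomal_median'`` (for a second pass after a
    first-round classification).
    """
    if normalization not in ("genome_median", "autosomal_median"):
        raise ValueError("normalization must be genome_median or autosomal_median")
    f = cov_f.reset_index(drop=True)
    m = cov_m.reset_index(drop=True)
    same = (
        len(f) == len(m)
        and (f["chrom"] == m["chrom"]).all()
        and (f["start"] == m["start"]).all()
        and (f["end"] == m["end"]).all()
    )
    if not same:
        raise ValueError("female and male tracks are tiled differently")

    def _norm_const(df: pd.DataFrame) -> float:
        usable = df
        if "empty" in df.columns:
            usable = df[~df["empty"]]
        if normalization == "autosomal_median":
            if not autosome_chroms:
                raise ValueError("autosomal_median normalization needs autosome_chroms")
            usable = usable[usable["chrom"].isin(autosome_chroms)]
        if len(usable) == 0:
            raise ValueError("no usable windows for normalization")
        c = float(usable["depth"].median())
        if c <= 0:
            raise ValueError("normalization constant is zero")
        return c

    cf, cm = _norm_const(f), _norm_const(m)
    win = f[["chrom", "start", "end"]].copy()
    win["depth_f"] = f["depth"].to_numpy(dtype=float)
    win["depth_m"] = m["depth"].to_numpy(dtype=float)
    win["norm_f"] = win["depth_f"] / cf
    win["norm_m"] = win["depth_m"] / cm

    empty = np.zeros(len(win), dtype=bool)
    if "empty" in f.columns:
        empty |= f["empty"].to_numpy()
    if "empty" in m.columns:
        empty |= m["empty"].to_numpy()
    low_m = win["depth_m"].to_numpy() < min_m_depth
    flag = np.where(empty, "empty", np.where(low_m, "low_male_depth", ""))
    win["flag"] = flag
    valid = flag == ""
    ratio = np.full(len(win), np.nan)
    ratio[valid] = win.loc[valid, "norm_f"] / win.loc[valid, "norm_m"]
    win["ratio"] = ratio
    with np.errstate(divide="ignore"):
        win["log2_ratio"] = np.where(ratio > 0, np.log2(np.where(ratio > 0, ratio, 1.0)), np.nan)

    grp = win.groupby("chrom", sort=False)
    scaff = pd.DataFrame(
        {
            "median_ratio": grp["ratio"].median(),
            "n_windows": grp["ratio"].count(),
            "n_flagged": grp["flag"].apply(lambda s: int((s != "").sum())),
        }
    )
    scaff = scaff.loc[sorted(scaff.index, key=_natural_key)]
    scaff.index.name = "scaffold"
    return FMRatioTable(
        windows=win, scaffolds=scaff, norm_const_f=cf, norm_const_m=cm, normalization=normalization
    )


def classify_scaffolds(
    table: FMRatioTable,
    x_threshold: float = 1.6,
    y_threshold: float = 0.3,
    min_windows: int = 3,
) -> pd.DataFrame:
    """Call each scaffold autosomal, X-linked, Y-linked, or ambiguous.

    A scaffold is X-linked when its median normalized F/M ratio is at or
    above ``x_threshold`` (inclusive), Y-linked when at or below
    ``y_threshold`` with male depth above the floor, and ambiguous with fewer
    than ``min_windows`` informative windows.
    """
    if not (y_threshold < 1.0 < x_threshold):
        raise ValueError("thresholds must satisfy y_threshold < 1 < x_threshold")
    rows = []
    for scaffold, rec in table.scaffolds.iterrows():
        med = rec["median_ratio"]
        n = int(rec["n_windows"])
        if n < min_windows or not np.isfinite(med):
            call, note = "ambiguous", f"only {n} informative windows"
        elif med >= x_threshold:
            call, note = "X_linked", f"median F/M {med:.3g} >= {x_threshold}"
        elif med <= y_threshold:
            call, note = "Y_linked", f"median F/M {med:.3g} <= {y_threshold}"
        else:
            call, note = "autosomal", f"median F/M {med:.3g}"
        rows.append((scaffold, call, med, n, note))
    return pd.DataFrame(
        rows, columns=["scaffold", "call", "median_ratio", "n_windows", "note"]
    )


@dataclass
class DifferentiationScore:
    """Summary of neo-sex differentiation over a region.

    ``rel_male_depth`` is the mean normalized male depth relative to the
    autosomal reference and estimates (1 + theta)/2 for a neo-X whose neo-Y
    retains homology fraction theta.
    """

    chrom: str
    n_windows: int
    rel_male_depth: float
    frac_x_windows: float
    log2_sd: float


def differentiation_score(
    table: FMRatioTable,
    chrom: str,
    start: int | None = None,
    end: int | None = None,
    autosome_chroms: list[str] | None = None,
    x_threshold: float = 1.6,
    min_windows: int = 3,
) -> DifferentiationScore:
    """Quantify how far a region has differentiated from its Y partner."""
    win = table.windows
    in_chrom = win["chrom"] == chrom
    if not in_chrom.any():
        raise ValueError(f"region chromosome {chrom!r} not in tiling")
    region = in_chrom.copy()
    if start is not None:
        region &= win["end"] > start
    if end is not None:
        region &= win["start"] < end
    reg = win[region & (win["flag"] == "")]
    if len(reg) < min_windows:
        raise ValueError(f"region has {len(reg)} informative windows, fewer than {min_windows}")
    if autosome_chroms is not None:
        ref = win[win["chrom"].isin(autosome_chroms) & (win["flag"] == "")]
    else:
        ref = win[~region & (win["flag"] == "")]
    if len(ref) == 0:
        raise ValueError("no reference windows for relative male depth")
    rel = float(reg["norm_m"].mean() / ref["norm_m"].mean())
    frac = float((reg["ratio"] >= x_threshold).mean())
    sd = float(reg["log2_ratio"].std(ddof=1)) if len(reg) > 1 else 0.0
    return DifferentiationScore(
        chrom=chrom, n_windows=len(reg), rel_male_depth=rel, frac_x_windows=frac, log2_sd=sd
    )


@dataclass
class BreakpointEstimate:
    """Single changepoint in log2(F/M) along one chromosome.

    ``position`` is a window boundary in bp (None when no breakpoint was
    supported); ``ci`` is the window-index interval of boundaries whose total
    cost lies within ``ci_delta`` of the minimum.
    """

    chrom: str
    found: bool
    position: int | None
    boundary_index: int | None
    n_windows: int
    left_class: str
    right_class: str
    left_mean_log2: float
    right_mean_log2: float
    ci: tuple[int, int] | None
    gain: float


def _segment_costs(v: np.ndarray) -> tuple[np.ndarray, float]:
    """Total within-segment squared error for every split of ``v``; and no-split cost."""
    n = len(v)
    s1 = np.concatenate([[0.0], np.cumsum(v)])
    s2 = np.concatenate([[0.0], np.cumsum(v * v)])

    def ss(i: int, j: int) -> float:
        s = s1[j] - s1[i]
        return float(s2[j] - s2[i] - s * s / (j - i))

    costs = np.array([ss(0, b) + ss(b, n) for b in range(1, n)])
    return costs, ss(0, n)


def _ratio_class(mean_log2: float, x_threshold: float, y_threshold: float) -> str:
    if mean_log2 >= np.log2(x_threshold):
        return "X_linked"
    if mean_log2 <= np.log2(y_threshold):
        return "Y_linked"
    return "autosomal"


def detect_breakpoint(
    table: FMRatioTable,
    chrom: str,
    min_gain: float = 0.10,
    ci_delta: float = 1.0,
    x_threshold: float = 1.6,
    y_threshold: float = 0.3,
) -> BreakpointEstimate:
    """Locate the anc-X/neo-X boundary by exhaustive least-squares scan.

    Scans every window boundary for the single split minimizing the total
    within-segment squared error of log2(F/M); reports "no breakpoint" when
    the best split reduces the no-split cost by less than ``min_gain``
    (fraction).  Flagged windows are excluded from the scan.
    """
    win = table.windows
    sel = win[(win["chrom"] == chrom)].sort_values("start", kind="stable")
    if len(sel) == 0:
        raise ValueError(f"chromosome {chrom!r} not in tiling")
    ok = sel[(sel["flag"] == "") & np.isfinite(sel["log2_ratio"])]
    if len(ok) == 0:
        raise ValueError(f"all windows on {chrom} are flagged; cannot scan for a breakpoint")
    v = ok["log2_ratio"].to_numpy(dtype=float)
    n = len(v)
    if n < 10:
        raise ValueError(f"breakpoint scan needs >= 10 informative windows, got {n}")
    costs, cost0 = _segment_costs(v)
    b = int(np.argmin(costs)) + 1
    gain = float((cost0 - costs[b - 1]) / cost0) if cost0 > 0 else 0.0
    found = cost0 > 0 and gain >= min_gain
    left = float(np.mean(v[:b]))
    right = float(np.mean(v[b:]))
    ci_idx = np.flatnonzero(costs <= costs[b - 1] + ci_delta) + 1
    starts = ok["start"].to_numpy()
    est = BreakpointEstimate(
        chrom=chrom,
        found=found,
        position=int(starts[b]) if found else None,
        boundary_index=b if found else None,
        n_windows=n,
        left_class=_ratio_class(left, x_threshold, y_threshold),
        right_class=_ratio_class(right, x_threshold, y_threshold),
        left_mean_log2=left,
        right_mean_log2=right,
        ci=(int(ci_idx.min()), int(ci_idx.max())) if found else None,
        gain=gain,
    )
    return est
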