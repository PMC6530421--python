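"""Regional and chromosome-level interference summaries.

Each linkage group's map span is divided into three equal-length regions
(NO.1, NO.2, NO.3).  Differences between the binned distributions of an
interference measure (C4 by default) in two regions are quantified with the
L1 histogram distance

    delta = sum_i |p_i1 - p_i2|,   0 <= delta <= 2,

zero when the binned distributions coincide and 2 when they share no bin.
Chromosome-level summaries (five-number boxplot statistics and the mean) feed
ordinary least-squares fits of mean interference strength on map length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .io import GeneticMap
from .scan import ScanRecord

__all__ = [
    "RegionComparison",
    "ChromosomeSummary",
    "REGION_LABELS",
    "assign_regions",
    "delta_statistic",
    "difference_ratios",
    "region_values",
    "chromosome_summaries",
    "length_fit",
]

REGION_LABELS = ("NO.1", "NO.2", "NO.3")
DEFAULT_BINS = 10


@dataclass(frozen=True)
class RegionComparison:
    """Binned comparison of an interference measure between two regions."""

    region_a: str
    region_b: str
    p1: np.ndarray
    p2: np.ndarray
    bin_edges: np.ndarray
    delta: float
    normalized: bool = True


@dataclass(frozen=True)
class ChromosomeSummary:
    """Per-linkage-group distribution summary of an interference measure."""

    lg: str
    length_cM: float
    mean_C: float
    median_C: float
    q1: float
    q3: float
    min: float
    max: float
    n_windows: int
    n_undefined: int

    @property
    def iqr_C(self) -> float:
        return self.q3 - self.q1


def assign_regions(gmap: GeneticMap, lg: str, positions, k: int = 3) -> list[str]:
    """Region label for each representative position on one linkage group.

    The group's cM span is split into ``k`` equal-length half-open intervals
    [start, start+L/k), ...; the last interval is closed so the terminal
    marker belongs to the final region.
    """
    lo, hi = gmap.span(lg)
    length = hi - lo
    labels = REGION_LABELS if k == 3 else tuple(f"NO.{i + 1}" for i in range(k))
    out = []
    for pos in positions:
        if length == 0:
            out.append(labels[0])
            continue
        idx = int(np.floor((pos - lo) / length * k))
        idx = min(max(idx, 0), k - 1)
        out.append(labels[idx])
    return out


def delta_statistic(
    values_a,
    values_b,
    bins: int | np.ndarray = DEFAULT_BINS,
    region_a: str = "NO.1",
    region_b: str = "NO.2",
    normalized: bool = True,
) -> RegionComparison:
    """L1 distance between the binned distributions of two value lists.

    Shared bin edges are computed from the pooled values (``bins`` equal-width
    bins) unless explicit edges are passed.  With ``normalized=True`` (the
    default) each histogram is converted to proportions, giving the bounded
    statistic delta in [0, 2]; with ``normalized=False`` raw counts are
    differenced (the unnormalized "difference sum" reading).
    """
    a = np.asarray([v for v in values_a if np.isfinite(v)], dtype=float)
    b = np.asarray([v for v in values_b if np.isfinite(v)], dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty region: comparison is absent, not zero")
    if np.isscalar(bins):
        pooled = np.concatenate([a, b])
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    h1 = np.histogram(a, bins=edges)[0].astype(float)
    h2 = np.histogram(b, bins=edges)[0].astype(float)
    if normalized:
        h1 /= h1.sum()
        h2 /= h2.sum()
    return RegionComparison(
        region_a=region_a,
        region_b=region_b,
        p1=h1,
        p2=h2,
        bin_edges=edges,
        delta=float(np.abs(h1 - h2).sum()),
        normalized=normalized,
    )


def region_values(
    records: list[ScanRecord],
    gmap: GeneticMap,
    lg: str | None = None,
    strength: str = "C4",
    k: int = 3,
) -> dict[str, list[float]]:
    """Defined strength values per region, for one lg or pooled genome-wide.

    Undefined (NaN) coefficients and skipped windows are excluded.
    """
    labels = REGION_LABELS if k == 3 else tuple(f"NO.{i + 1}" for i in range(k))
    out: dict[str, list[float]] = {lab: [] for lab in labels}
    lgs = [lg] if lg is not None else list({rec.lg for rec in records})
    for group in lgs:
        recs = [r for r in records if r.lg == group and r.method != "skipped"]
        if not recs:
            continue
        assigned = assign_regions(gmap, group, [r.midpoint for r in recs], k=k)
        for rec, lab in zip(recs, assigned):
            v = rec.strength(strength)
            if np.isfinite(v):
                out[lab].append(v)
    return out


def difference_ratios(
    records: list[ScanRecord],
    gmap: GeneticMap,
    strength: str = "C4",
    bins: int = DEFAULT_BINS,
    normalized: bool = True,
) -> dict[str, dict[str, float]]:
    """Per-linkage-group region-pair difference ratios.

    For each lg, the delta statistic between the strength distributions of
    (NO.1, NO.2), (NO.2, NO.3) and (NO.1, NO.3); a pair with an empty region
    is reported as NaN (absent), never zero.
    """
    pairs = [("NO.1", "NO.2"), ("NO.2", "NO.3"), ("NO.1", "NO.3")]
    out: dict[str, dict[str, float]] = {}
    for lg in gmap.linkage_groups():
        vals = region_values(records, gmap, lg=lg, strength=strength)
        row = {}
        for ra, rb in pairs:
            key = f"{ra}-{rb}"
            try:
                row[key] = delta_statistic(
                    vals[ra], vals[rb], bins=bins,
                    region_a=ra, region_b=rb, normalized=normalized,
                ).delta
            except ValueError:
                row[key] = float("nan")
        out[lg] = row
    return out


def chromosome_summaries(
    records: list[ScanRecord],
    gmap: GeneticMap,
    strength: str = "C4",
) -> list[ChromosomeSummary]:
    """Five-number summary plus mean of the strength measure per linkage
    group (quartiles by linear interpolation between order statistics);
    groups with no defined value are omitted."""
    out = []
    for lg in gmap.linkage_groups():
        vals = [
            rec.strength(strength)
            for rec in records
            if rec.lg == lg and rec.method != "skipped"
        ]
        defined = np.asarray([v for v in vals if np.isfinite(v)])
        if defined.size == 0:
            continue
        lo, hi = gmap.span(lg)
        q1, med, q3 = np.percentile(defined, [25, 50, 75])  # linear interp
        out.append(
            ChromosomeSummary(
                lg=lg,
                length_cM=hi - lo,
                mean_C=float(defined.mean()),
                median_C=float(med),
                q1=float(q1),
                q3=float(q3),
                min=float(defined.min()),
                max=float(defined.max()),
                n_windows=len(vals),
                n_undefined=len(vals) - defined.size,
            )
        )
    return out


def length_fit(
    summaries: list[ChromosomeSummary],
    group_a,
    exclude=(),
) -> dict[str, dict[str, float]]:
    """OLS fits of mean interference strength on chromosome map length.

    ``group_a`` names the lgs fitted together as one group; all remaining
    (non-excluded) lgs form group "b".  Returns per group the slope,
    intercept, adjusted R-squared and n.  Each group needs >= 3 chromosomes
    and non-constant lengths.
    """
    group_a = {str(x) for x in group_a}
    exclude = {str(x) for x in exclude}
    kept = [s for s in summaries if s.lg not in exclude]
    groups = {
        "a": [s for s in kept if s.lg in group_a],
        "b": [s for s in kept if s.lg not in group_a],
    }
    out = {}
    for name, grp in groups.items():
        if len(grp) < 3:
            raise ValueError(f"group {name!r} has {len(grp)} chromosomes; need >= 3")
        x = np.array([s.length_cM for s in grp])
        y = np.array([s.mean_C for s in grp])
        if np.ptp(x) == 0:
            raise ValueError(f"group {name!r} has constant chromosome length")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        out[name] = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "adj_r_squared": float(fit.rsquared_adj),
            "n": len(grp),
            "lgs": sorted(s.lg for s in grp),
        }
    return out
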