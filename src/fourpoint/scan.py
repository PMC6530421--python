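"""Genome scan: per-window interference landscape over a genetic map.

Each linkage group is partitioned into ordered four-marker windows
(disjoint consecutive quadruples by default, or stride-1 sliding windows);
each window is estimated via :mod:`fourpoint.model` and summarized as a
:class:`ScanRecord` holding the six recombination fractions and four
coincidence coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import (
    CoCProfile,
    GameteFrequencies,
    RecombinationProfile,
    coincidence_coefficients,
    recombination_fractions,
)
from .io import GeneticMap, GenotypeMatrix
from .model import DEFAULT_SEED, FourPointModel

logger = logging.getLogger(__name__)

__all__ = ["ScanRecord", "make_windows", "scan"]


@dataclass(frozen=True)
class ScanRecord:
    """One four-marker window of the interference landscape."""

    lg: str
    markers: tuple[str, str, str, str]
    positions: tuple[float, float, float, float]
    r: RecombinationProfile | None
    coc: CoCProfile | None
    method: str  # em | direct | skipped
    n_used: int
    gamete_freqs: GameteFrequencies | None = None

    @property
    def midpoint(self) -> float:
        """Representative map position: midpoint of the outer markers."""
        return 0.5 * (self.positions[0] + self.positions[3])

    def strength(self, selector: str = "C4") -> float:
        """Selected interference measure (C1..C4); NaN if undefined/skipped."""
        if self.coc is None:
            return float("nan")
        k = {"C1": 0, "C2": 1, "C3": 2, "C4": 3}[selector]
        return float(self.coc.as_array()[k])


def make_windows(gmap: GeneticMap, scheme: str = "nonoverlap"):
    """Ordered four-marker windows per linkage group.

    "nonoverlap": consecutive disjoint quadruples in map order, trailing
    remainder (<4 markers) dropped; "sliding": every stride-1 quadruple.
    """
    if scheme not in ("nonoverlap", "sliding"):
        raise ValueError(f"unknown windowing scheme {scheme!r}")
    windows = []
    for lg in gmap.linkage_groups():
        sub = gmap.markers_of(lg)
        names = list(sub["name"])
        m = len(names)
        if m < 4:
            logger.info("linkage group %s has %d markers; no windows", lg, m)
            continue
        if scheme == "nonoverlap":
            starts = range(0, m - 3, 4)
        else:
            starts = range(0, m - 3)
        for s in starts:
            windows.append((lg, tuple(names[s : s + 4])))
    return windows


def scan(
    gmap: GeneticMap,
    matrix: GenotypeMatrix,
    scheme: str = "nonoverlap",
    seed: int = DEFAULT_SEED,
    **fit_kwargs,
) -> list[ScanRecord]:
    """Estimate every window of the map and return the landscape records.

    A window that cannot be estimated (mixed segregation types, no usable
    individuals) yields a record with method="skipped"; the scan never
    aborts.  Deterministic given (inputs, seed): window ``k`` uses seed+k
    for any stochastic EM restart.
    """
    records = []
    for k, (lg, markers) in enumerate(make_windows(gmap, scheme)):
        positions = tuple(gmap.position(m) for m in markers)
        seg = {gmap.seg_type(m) for m in markers}
        res = None
        if len(seg) == 1:
            try:
                model = FourPointModel.from_matrix(matrix, markers, gmap)
                res = model.fit(seed=seed + k, **fit_kwargs)
            except ValueError as exc:
                logger.warning("window %s/%s skipped: %s", lg, markers[0], exc)
        else:
            logger.info(
                "window %s/%s skipped: mixed segregation types %s",
                lg, markers[0], sorted(seg),
            )
        if res is None:
            records.append(
                ScanRecord(
                    lg=lg, markers=markers, positions=positions,
                    r=None, coc=None, method="skipped", n_used=0,
                )
            )
            continue
        g = res.gamete_freqs
        records.append(
            ScanRecord(
                lg=lg,
                markers=markers,
                positions=positions,
                r=recombination_fractions(g),
                coc=coincidence_coefficients(g),
                method=model.method,
                n_used=res.n_used,
                gamete_freqs=g,
            )
        )
    return records
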