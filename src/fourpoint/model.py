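"""Estimation of gamete-type frequencies from a four-marker window.

The central object is :class:`FourPointModel`, built from the 81-class
genotype counts of one ordered marker quadruple (statsmodels-style: the model
holds the data and likelihood, ``fit()`` returns a results object carrying
the estimates and diagnostics).

Two estimation routes exist, dispatched on the window's segregation type:

* ``hk_hk`` (both parents heterozygous): offspring genotypes confound which
  parent contributed which gamete, so the eight shared gamete-type
  frequencies are estimated by EM on the 81-class multinomial mixture whose
  components are products of parental gamete-type frequencies.
* ``lm_ll`` / ``nn_np`` (testcross): offspring genotypes reveal the
  informative parent's gamete directly, so frequencies are simple counts.

Module-level functions (``count_genotypes``, ``em_estimate``,
``direct_gamete_estimate``, ``estimate_window``) offer the same machinery as
a plain functional surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    CLASS_LABELS,
    HAPLOTYPE_TYPE,
    N_CLASSES,
    N_TYPES,
    TYPE_LABELS,
    CoCProfile,
    GameteFrequencies,
    RecombinationProfile,
    classify_offspring,
    coincidence_coefficients,
    pair_structure,
    recombination_fractions,
)
from .io import GeneticMap, GenotypeMatrix

__all__ = [
    "GenotypeCountTable",
    "FourPointModel",
    "FourPointResults",
    "EMResult",
    "count_genotypes",
    "em_estimate",
    "direct_gamete_estimate",
    "estimate_window",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20190515


@dataclass(frozen=True)
class GenotypeCountTable:
    """Observed counts of the 81 four-marker genotype classes.

    ``counts`` is indexed as in :func:`fourpoint.core.classify_offspring`;
    ``n_used`` individuals contributed, ``n_dropped`` were excluded for
    missing calls in the window.
    """

    counts: np.ndarray
    n_dropped: int = 0

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (N_CLASSES,) or np.any(c < 0):
            raise ValueError("counts must be 81 non-negative integers")
        object.__setattr__(self, "counts", c.astype(float))

    @property
    def n_used(self) -> int:
        return int(self.counts.sum())


def count_genotypes(matrix: GenotypeMatrix, window) -> GenotypeCountTable:
    """Tally a family's calls at an ordered marker quadruple into the 81
    genotype classes; individuals with any missing call are dropped
    window-wise."""
    calls = matrix.window(window)
    complete = ~np.isnan(calls).any(axis=1)
    used = calls[complete].astype(int)
    idx = 27 * used[:, 0] + 9 * used[:, 1] + 3 * used[:, 2] + used[:, 3]
    counts = np.bincount(idx, minlength=N_CLASSES)
    return GenotypeCountTable(counts=counts, n_dropped=int((~complete).sum()))


class FourPointModel:
    """Four-locus gamete-frequency model for one marker window.

    Parameters
    ----------
    counts : GenotypeCountTable or array-like of 81 counts
        Observed genotype-class counts.
    method : {"em", "direct"}
        "em" fits the shared parental gamete-frequency vector by EM on the
        full-sib genotype mixture (hk_hk windows); "direct" decodes each
        offspring's calls to the informative parent's gamete (testcross
        windows, calls restricted to {2, 1}).
    """

    def __init__(self, counts, method: str = "em"):
        if not isinstance(counts, GenotypeCountTable):
            counts = GenotypeCountTable(np.asarray(counts))
        if method not in ("em", "direct"):
            raise ValueError(f"unknown method {method!r}")
        if counts.n_used == 0:
            raise ValueError("no usable individuals: all counts are zero")
        self.counts = counts
        self.method = method
        self._cls, self._tm, self._tp, self._mult = pair_structure()

    # -- likelihood ------------------------------------------------------
    def class_probs(self, g) -> np.ndarray:
        """Model probabilities of the 81 classes at gamete frequencies g
        (shared by both parents)."""
        g = np.asarray(g, dtype=float)
        w = self._mult * g[self._tm] * g[self._tp] / 4.0
        return np.bincount(self._cls, weights=w, minlength=N_CLASSES)

    def loglike(self, g) -> float:
        p = self.class_probs(g)
        obs = self.counts.counts > 0
        if np.any(p[obs] <= 0.0):
            return -np.inf
        return float(np.sum(self.counts.counts[obs] * np.log(p[obs])))

    @classmethod
    def from_matrix(
        cls,
        matrix: GenotypeMatrix,
        window,
        genetic_map: GeneticMap | None = None,
        method: str | None = None,
    ) -> "FourPointModel":
        """Build the model from a genotype matrix and a marker quadruple,
        inferring the estimation route from the map's segregation types."""
        if method is None:
            if genetic_map is None:
                method = "em"
            else:
                seg = {genetic_map.seg_type(m) for m in window}
                if len(seg) > 1:
                    raise ValueError(f"window mixes segregation types {sorted(seg)}")
                method = "em" if seg == {"hk_hk"} else "direct"
        return cls(count_genotypes(matrix, window), method=method)

    # -- fitting ---------------------------------------------------------
    def fit(
        self,
        init="uniform",
        tol: float = 1e-8,
        max_iter: int = 5000,
        seed: int = DEFAULT_SEED,
    ) -> "FourPointResults":
        if self.method == "direct":
            return self._fit_direct()
        return self._fit_em(init=init, tol=tol, max_iter=max_iter, seed=seed)

    def _fit_direct(self) -> "FourPointResults":
        counts = self.counts.counts
        type_counts = np.zeros(N_TYPES)
        n_bad = 0.0
        for idx in np.flatnonzero(counts):
            digits = [int(ch) for ch in CLASS_LABELS[idx]]
            if any(d == 0 for d in digits):
                # code 0 cannot arise in a testcross window (informative
                # parent's gamete plus a constant allele); drop and warn
                n_bad += counts[idx]
                continue
            h = sum((d - 1) << k for d, k in zip(digits, (3, 2, 1, 0)))
            type_counts[HAPLOTYPE_TYPE[h]] += counts[idx]
        if n_bad:
            warnings.warn(
                f"{int(n_bad)} individual(s) with calls inconsistent with a "
                "testcross window were dropped",
                stacklevel=3,
            )
        n = type_counts.sum()
        if n == 0:
            raise ValueError("no testcross-consistent individuals in window")
        g_hat = GameteFrequencies(type_counts / n)
        ll = float(
            np.sum(type_counts[type_counts > 0] * np.log(g_hat.g[type_counts > 0]))
        )
        return FourPointResults(
            model=self,
            gamete_freqs=g_hat,
            loglik_trace=np.array([ll]),
            n_iter=0,
            converged=True,
            n_inconsistent=int(n_bad),
        )

    def _fit_em(self, init, tol, max_iter, seed) -> "FourPointResults":
        counts = self.counts.counts
        n_used = counts.sum()
        if isinstance(init, str):
            if init != "uniform":
                raise ValueError(f"unknown init {init!r}")
            g = np.full(N_TYPES, 1.0 / N_TYPES)
        elif isinstance(init, GameteFrequencies):
            g = init.g.copy()
        else:
            g = GameteFrequencies(np.asarray(init, dtype=float)).g.copy()

        cls, tm, tp, mult = self._cls, self._tm, self._tp, self._mult
        obs = counts > 0
        trace = []
        jittered = False
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pair_w = mult * g[tm] * g[tp]          # 4 * component probabilities
            p_cls = np.bincount(cls, weights=pair_w, minlength=N_CLASSES)
            if np.any(p_cls[obs] < 1e-300):
                # an observed class has (numerically) zero probability under
                # the current g: re-initialize once with a seeded jitter
                if jittered:
                    raise ValueError(
                        "observed genotype class has zero model probability"
                    )
                rng = np.random.default_rng(seed)
                g = 0.5 * g + 0.5 * rng.dirichlet(np.ones(N_TYPES))
                g /= g.sum()
                jittered = True
                continue
            trace.append(
                float(np.sum(counts[obs] * (np.log(p_cls[obs]) - np.log(4.0))))
            )
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(p_cls > 0, counts / np.where(p_cls > 0, p_cls, 1.0), 0.0)
            resp = pair_w * scale[cls]
            # each component carries one maternal and one paternal gamete
            type_counts = np.bincount(tm, weights=resp, minlength=N_TYPES)
            type_counts += np.bincount(tp, weights=resp, minlength=N_TYPES)
            g_new = type_counts / (2.0 * n_used)
            delta = np.max(np.abs(g_new - g))
            g = g_new
            if delta < tol:
                converged = True
                break
        g_hat = GameteFrequencies(g / g.sum())
        return FourPointResults(
            model=self,
            gamete_freqs=g_hat,
            loglik_trace=np.array(trace),
            n_iter=it,
            converged=converged,
        )


@dataclass
class FourPointResults:
    """Fit results for one four-marker window.

    Carries the estimated gamete-type frequencies and the derived
    recombination fractions and coincidence coefficients, plus EM
    diagnostics (log-likelihood trace, iteration count, convergence flag).
    """

    model: FourPointModel
    gamete_freqs: GameteFrequencies
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    n_inconsistent: int = 0
    _r: RecombinationProfile | None = field(default=None, repr=False)
    _coc: CoCProfile | None = field(default=None, repr=False)

    @property
    def params(self) -> np.ndarray:
        return self.gamete_freqs.g

    @property
    def recombination(self) -> RecombinationProfile:
        if self._r is None:
            self._r = recombination_fractions(self.gamete_freqs)
        return self._r

    @property
    def coincidence(self) -> CoCProfile:
        if self._coc is None:
            self._coc = coincidence_coefficients(self.gamete_freqs)
        return self._coc

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1]) if len(self.loglik_trace) else float("nan")

    @property
    def n_used(self) -> int:
        return self.model.counts.n_used

    def summary(self) -> str:
        g = self.gamete_freqs
        r = self.recombination
        c = self.coincidence
        lines = [
            "Four-point linkage fit",
            "=" * 58,
            f"method: {self.model.method:>8s}    n_used: {self.n_used}"
            f"    dropped: {self.model.counts.n_dropped}",
            f"converged: {str(self.converged):>5s}    iterations: {self.n_iter}"
            f"    log-likelihood: {self.llf:.4f}",
            "-" * 58,
            "gamete-type frequencies",
        ]
        lines += [f"  {lab}: {g[t]:.6f}" for t, lab in enumerate(TYPE_LABELS)]
        lines.append("recombination fractions")
        lines += [
            f"  {name[2:].upper():>2s}: {val:.4f}"
            for name, val in zip(RecombinationProfile.FIELDS, r.as_array())
        ]
        lines.append("coincidence coefficients (1 = no interference)")
        lines += [
            f"  C{k + 1}: " + ("undefined" if np.isnan(v) else f"{v:.4f}")
            for k, v in enumerate(c.as_array())
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EMResult:
    """Thin functional wrapper around an EM fit."""

    g_hat: GameteFrequencies
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool


def em_estimate(
    counts: GenotypeCountTable,
    init="uniform",
    tol: float = 1e-8,
    max_iter: int = 5000,
    seed: int = DEFAULT_SEED,
) -> EMResult:
    """EM estimate of the shared parental gamete frequencies from 81-class
    genotype counts of an hk_hk window."""
    res = FourPointModel(counts, method="em").fit(
        init=init, tol=tol, max_iter=max_iter, seed=seed
    )
    return EMResult(
        g_hat=res.gamete_freqs,
        loglik_trace=res.loglik_trace,
        n_iter=res.n_iter,
        converged=res.converged,
    )


def direct_gamete_estimate(
    matrix: GenotypeMatrix,
    window,
    informative_parent: str = "maternal",
) -> GameteFrequencies:
    """Gamete-type frequencies by direct counting in a testcross window.

    Each offspring's calls (restricted to {2,1}) decode to the informative
    parent's gamete; frequencies are counts over used individuals.  Which
    parent is informative does not change the decoding, only its
    interpretation.
    """
    if informative_parent not in ("maternal", "paternal"):
        raise ValueError(f"informative_parent={informative_parent!r}")
    res = FourPointModel(count_genotypes(matrix, window), method="direct").fit()
    return res.gamete_freqs


def estimate_window(
    matrix: GenotypeMatrix,
    window,
    genetic_map: GeneticMap,
    **fit_kwargs,
):
    """Dispatch estimation for a window by its segregation types.

    Returns ``(GameteFrequencies | None, method)`` where method is "em",
    "direct", or "skipped" (mixed segregation types, or estimation failure).
    """
    lgs = {genetic_map.markers.set_index("name").loc[m, "linkage_group"] for m in window}
    if len(lgs) > 1:
        raise ValueError(f"window spans linkage groups {sorted(lgs)}")
    seg = {genetic_map.seg_type(m) for m in window}
    if len(seg) > 1:
        return None, "skipped"
    try:
        model = FourPointModel.from_matrix(matrix, window, genetic_map)
        res = model.fit(**fit_kwargs)
    except ValueError:
        return None, "skipped"
    return res.gamete_freqs, model.method
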