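"""Simulation of full-sib F2 families with known interference structure.

The generator is parameterized at the window level: each four-marker window
carries its own true gamete-type frequency vector, specified either directly
or through interval recombination fractions plus coincidence coefficients
(inverting the defining CoC ratios).  Offspring are formed by drawing one
maternal and one paternal gamete per individual from the 16-haplotype
expansion of the type frequencies and coding the union to {2,1,0} calls
(or to testcross {2,1} calls for single-parent-informative windows).

No chiasma process is modelled along the chromosome: windows are mutually
independent, matching the analysis unit of the scan.  Defaults echo a
full-sib mapping study's scale: 19 linkage groups spanning roughly 130-530
cM and a family of 408 offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import (
    HAPLOTYPE_TYPE,
    N_TYPES,
    TYPE_LABELS,
    GameteFrequencies,
    coincidence_coefficients,
    recombination_fractions,
)
from .io import (
    GeneticMap,
    GenotypeMatrix,
    write_genetic_map,
    write_genotype_matrix,
    write_truth,
)

__all__ = [
    "SimulationTruth",
    "StudyConfig",
    "gametes_from_r_and_coc",
    "coc_feasible",
    "simulate_family",
    "testcross_encode",
    "simulate_study",
]

DEFAULT_SEED = 20190515


def gametes_from_r_and_coc(
    r_ab: float,
    r_bc: float,
    r_cd: float,
    c1: float = 1.0,
    c2: float = 1.0,
    c3: float = 1.0,
    c4: float = 1.0,
) -> GameteFrequencies:
    """Invert the coincidence-coefficient definitions to gamete frequencies.

    g111 = C4 r_AB r_BC r_CD, g110 = C1 r_AB r_BC - g111, etc.; the remaining
    single- and zero-crossover types follow from the interval marginals.  Not
    every (r, C) combination corresponds to a probability vector — an
    infeasible combination raises, naming the first negative entry.
    """
    for name, v in (("r_ab", r_ab), ("r_bc", r_bc), ("r_cd", r_cd),
                    ("C1", c1), ("C2", c2), ("C3", c3), ("C4", c4)):
        if v < 0 or not np.isfinite(v):
            raise ValueError(f"{name}={v} must be finite and non-negative")
    g111 = c4 * r_ab * r_bc * r_cd
    g110 = c1 * r_ab * r_bc - g111
    g011 = c2 * r_bc * r_cd - g111
    g101 = c3 * r_ab * r_cd - g111
    g100 = r_ab - g111 - g110 - g101
    g010 = r_bc - g111 - g110 - g011
    g001 = r_cd - g111 - g101 - g011
    rest = g111 + g110 + g011 + g101 + g100 + g010 + g001
    g000 = 1.0 - rest
    g = np.array([g000, g001, g010, g011, g100, g101, g110, g111])
    bad = np.flatnonzero(g < -1e-12)
    if bad.size:
        t = int(bad[np.argmin(g[bad])])
        raise ValueError(
            f"infeasible (r, C) combination: {TYPE_LABELS[t]} = {g[t]:.4g} < 0"
        )
    return GameteFrequencies(np.clip(g, 0.0, None))


def coc_feasible(r, coc) -> tuple[bool, str | None]:
    """Whether a valid gamete-frequency vector exists for interval fractions
    ``r = (r_AB, r_BC, r_CD)`` and coefficients ``coc = (C1..C4)``; on
    failure also returns the first violated gamete-type label."""
    try:
        gametes_from_r_and_coc(*r, *coc)
    except ValueError as exc:
        label = str(exc).split(":")[-1].split("=")[0].strip()
        return False, label
    return True, None


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_haplotypes(g: GameteFrequencies, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(16, size=n, p=g.haplotype_probs())


def _haplotype_bits(h: np.ndarray) -> np.ndarray:
    """(n, 4) matrix of parental-phase indicators for haplotype codes."""
    return np.stack([(h >> k) & 1 for k in (3, 2, 1, 0)], axis=1)


def simulate_family(
    g_maternal: GameteFrequencies,
    g_paternal: GameteFrequencies | None = None,
    n: int = 408,
    seed=DEFAULT_SEED,
    markers=("M1", "M2", "M3", "M4"),
    seg_type: str = "hk_hk",
) -> GenotypeMatrix:
    """Simulate one four-marker window for a full-sib family of size ``n``.

    Each offspring combines one maternal and one paternal gamete drawn from
    the 16-haplotype expansion (g_t/2 per complementary haplotype).  hk_hk
    windows are coded as allele counts {2,1,0}; testcross windows code only
    the informative parent's gamete (calls in {2,1}).
    """
    if n < 1:
        raise ValueError("family size must be >= 1")
    if g_paternal is None:
        g_paternal = g_maternal
    rng = _rng(seed)
    hm = _draw_haplotypes(g_maternal, n, rng)
    hp = _draw_haplotypes(g_paternal, n, rng)
    if seg_type == "hk_hk":
        calls = _haplotype_bits(hm) + _haplotype_bits(hp)
    elif seg_type in ("lm_ll", "nn_np"):
        informative = hm if seg_type == "lm_ll" else hp
        return testcross_encode(informative, seg_type, markers=markers)
    else:
        raise ValueError(f"unknown seg_type {seg_type!r}")
    df = pd.DataFrame(
        calls.astype(float),
        index=pd.Index([f"F2_{i + 1:04d}" for i in range(n)], name="id"),
        columns=list(markers),
    )
    return GenotypeMatrix(df)


def testcross_encode(
    gamete_draws: np.ndarray,
    seg_type: str,
    markers=("M1", "M2", "M3", "M4"),
) -> GenotypeMatrix:
    """Code the informative parent's gametes as testcross offspring calls.

    The informative parent's allele determines heterozygous versus
    homozygous at each marker (parental-phase allele -> 2, alternate -> 1);
    the uninformative parent contributes a constant allele.  Decoding
    ``call - 1`` per marker recovers the gamete exactly.
    """
    if seg_type not in ("lm_ll", "nn_np"):
        raise ValueError(f"seg_type {seg_type!r} is not a testcross configuration")
    h = np.asarray(gamete_draws)
    calls = _haplotype_bits(h) + 1
    df = pd.DataFrame(
        calls.astype(float),
        index=pd.Index([f"F2_{i + 1:04d}" for i in range(len(h))], name="id"),
        columns=list(markers),
    )
    return GenotypeMatrix(df)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of a simulated study: per-window gamete frequencies,
    recombination fractions and coincidence coefficients, plus the seed and
    family size."""

    windows: list[dict]
    seed: int
    n: int

    def window_for(self, markers) -> dict:
        key = tuple(markers)
        for w in self.windows:
            if tuple(w["markers"]) == key:
                return w
        raise KeyError(f"no truth recorded for window {key}")


@dataclass
class StudyConfig:
    """Configuration of a simulated full-sib interference study.

    Geometry defaults echo a 19-linkage-group map spanning ~130-530 cM with
    a family of 408 offspring; 40 markers per group keep runs desk-scale.
    Interference truth is set per window from ``base_r`` and ``base_coc``;
    optionally the triple-interval coefficient C4 varies linearly with
    linkage-group length (``c4_range``) and/or is multiplied by
    ``mid_c4_factor`` for windows in the middle third of their group.
    """

    n_lgs: int = 19
    markers_per_lg: int = 40
    lg_length_min: float = 130.26
    lg_length_max: float = 530.03
    family_size: int = 408
    seg_pattern: tuple[str, ...] = ("hk_hk", "lm_ll", "nn_np")
    base_r: tuple[float, float, float] = (0.2, 0.2, 0.2)
    base_coc: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    c4_range: tuple[float, float] | None = None
    mid_c4_factor: float = 1.0
    seed: int = DEFAULT_SEED

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("seg_pattern", "base_r", "base_coc", "c4_range"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("seg_pattern", "base_r", "base_coc", "c4_range"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def _lg_lengths(config: StudyConfig) -> np.ndarray:
    if config.n_lgs == 1:
        return np.array([config.lg_length_min])
    return np.linspace(config.lg_length_min, config.lg_length_max, config.n_lgs)


def _window_coc(config: StudyConfig, lg_length: float, mid: bool) -> tuple:
    c1, c2, c3, c4 = config.base_coc
    if config.c4_range is not None:
        lo, hi = config.c4_range
        span = config.lg_length_max - config.lg_length_min
        frac = 0.0 if span == 0 else (lg_length - config.lg_length_min) / span
        c4 = lo + frac * (hi - lo)
    if mid:
        c4 = c4 * config.mid_c4_factor
    return c1, c2, c3, c4


def simulate_study(
    config: StudyConfig | None = None,
    out_dir=None,
) -> tuple[GeneticMap, GenotypeMatrix, SimulationTruth]:
    """Generate a complete simulated study: map, genotype matrix, truth.

    Markers are evenly spaced along each linkage group; disjoint marker
    quadruples form the truth windows, each assigned a segregation type by
    cycling ``seg_pattern`` and a gamete-frequency truth from the config's
    (r, C) rules.  Trailing markers not filling a quadruple are simulated
    under the base parameters but carry no recorded truth.  With ``out_dir``
    set, map/genotype TSVs and a truth JSON are also written.
    """
    config = config or StudyConfig()
    lengths = _lg_lengths(config)
    ss = np.random.SeedSequence(config.seed)
    n = config.family_size
    ids = pd.Index([f"F2_{i + 1:04d}" for i in range(n)], name="id")

    map_rows = []
    columns: dict[str, np.ndarray] = {}
    truth_windows: list[dict] = []
    marker_counter = 0

    # windows: (lg, lg_length, positions, is_mid, seg_type, recorded)
    plans = []
    for lg_idx in range(config.n_lgs):
        lg = str(lg_idx + 1)
        length = float(lengths[lg_idx])
        m = config.markers_per_lg
        positions = np.linspace(0.0, length, m)
        w_idx = 0
        start = 0
        while start < m:
            stop = min(start + 4, m)
            pos = list(positions[start:stop])
            recorded = stop - start == 4
            # pad a trailing remainder so a full window can be simulated
            while len(pos) < 4:
                pos.append(pos[-1])
            mid_lo, mid_hi = length / 3.0, 2.0 * length / 3.0
            midpoint = 0.5 * (pos[0] + pos[3])
            is_mid = mid_lo <= midpoint < mid_hi
            seg = config.seg_pattern[w_idx % len(config.seg_pattern)]
            plans.append((lg, length, pos, stop - start, is_mid, seg, recorded))
            w_idx += 1
            start = stop

    child_rngs = [np.random.default_rng(s) for s in ss.spawn(len(plans))]

    for (lg, length, pos, n_real, is_mid, seg, recorded), rng in zip(plans, child_rngs):
        coc = _window_coc(config, length, is_mid)
        try:
            g = gametes_from_r_and_coc(*config.base_r, *coc)
        except ValueError as exc:
            raise ValueError(
                f"infeasible truth for window at lg {lg}, {pos[0]:.2f} cM: {exc}"
            ) from exc
        names = []
        for _ in range(n_real):
            marker_counter += 1
            names.append(f"{seg}_{marker_counter:05d}")
        sim_names = names + [f"_pad{k}" for k in range(4 - n_real)]
        fam = simulate_family(
            g, n=n, seed=rng, markers=sim_names, seg_type=seg
        )
        for k, name in enumerate(names):
            map_rows.append((name, lg, float(pos[k]), seg))
            columns[name] = fam.calls.iloc[:, k].to_numpy()
        if recorded:
            r = recombination_fractions(g)
            c = coincidence_coefficients(g)
            truth_windows.append(
                {
                    "lg": lg,
                    "markers": names,
                    "positions": [float(p) for p in pos],
                    "seg_type": seg,
                    "g": list(g.g),
                    "r": list(r.as_array()),
                    "C": list(c.as_array()),
                }
            )

    gmap = GeneticMap(
        pd.DataFrame(map_rows, columns=["name", "linkage_group", "position_cM", "seg_type"])
    )
    matrix = GenotypeMatrix(pd.DataFrame(columns, index=ids))
    truth = SimulationTruth(windows=truth_windows, seed=config.seed, n=n)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = f"fourpoint simulate seed={config.seed}"
        write_genetic_map(gmap, out_dir / "map.tsv", header=header)
        write_genotype_matrix(matrix, out_dir / "genotypes.tsv", header=header)
        write_truth(truth, out_dir / "truth.json")
    return gmap, matrix, truth
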