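"""Four-locus gamete algebra for a phase-known full-sib cross.

A doubly heterozygous F1 parent with coupling-phase haplotypes ABCD/abcd
produces 16 distinct gametes over four ordered markers A-B-C-D.  Each gamete
is characterised by its crossover-indicator triple (i_AB, i_BC, i_CD): whether
an odd number of crossovers separated the alleles inherited at the flanking
markers of each interval.  Complementary gametes (e.g. ABCD and abcd) share
the same indicator triple, so the 16 gametes collapse into 8 *gamete types*
with frequencies g000 ... g111, each type splitting its mass equally between
its two complementary haplotypes.

Everything downstream — pairwise recombination fractions, coincidence
coefficients, and the 81-class genotype mixture for an F2 full-sib family —
is exact algebra on the vector (g000, ..., g111).  This module holds that
algebra; estimation lives in :mod:`fourpoint.model`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_TYPES",
    "N_HAPLOTYPES",
    "N_CLASSES",
    "TYPE_LABELS",
    "CLASS_LABELS",
    "GameteFrequencies",
    "RecombinationProfile",
    "CoCProfile",
    "GenotypeClassTable",
    "haplotype_type",
    "haplotype_calls",
    "classify_offspring",
    "class_label",
    "recombination_fractions",
    "coincidence_coefficients",
    "independence_gametes",
    "genotype_class_table",
    "pair_structure",
]

N_TYPES = 8          # gamete types (complementary pairs)
N_HAPLOTYPES = 16    # concrete 4-locus gametes
N_CLASSES = 81       # identifiable {2,1,0}^4 genotype classes

#: labels of the 8 gamete types in binary (i_AB, i_BC, i_CD) order
TYPE_LABELS = tuple(f"g{t:03b}" for t in range(N_TYPES))


def haplotype_type(h: int) -> int:
    """Gamete-type index (0..7) of haplotype ``h``.

    ``h`` encodes the 4-locus gamete as bits (A,B,C,D) = (bit3,...,bit0),
    bit 1 meaning the allele from the ABCD parental haplotype.  The type
    index packs the interval crossover indicators as 4*i_AB + 2*i_BC + i_CD.
    """
    a, b, c, d = (h >> 3) & 1, (h >> 2) & 1, (h >> 1) & 1, h & 1
    return 4 * (a ^ b) + 2 * (b ^ c) + (c ^ d)


def haplotype_calls(h_m: int, h_p: int) -> tuple[int, int, int, int]:
    """Per-marker genotype codes (counts of parental-phase alleles) of the
    offspring formed from maternal haplotype ``h_m`` and paternal ``h_p``."""
    return tuple(
        ((h_m >> k) & 1) + ((h_p >> k) & 1) for k in (3, 2, 1, 0)
    )


#: type index of each of the 16 haplotypes
HAPLOTYPE_TYPE = np.array([haplotype_type(h) for h in range(N_HAPLOTYPES)])

#: the two haplotypes making up each gamete type (complementary pair)
TYPE_HAPLOTYPES = tuple(
    tuple(h for h in range(N_HAPLOTYPES) if HAPLOTYPE_TYPE[h] == t)
    for t in range(N_TYPES)
)


def classify_offspring(calls) -> int:
    """Map four genotype codes in {2,1,0} to the class index 0..80.

    The index is the base-3 expansion 27*a + 9*b + 3*c + d of the calls
    (a,b,c,d); missing calls are not accepted here — callers drop such
    individuals window-wise.
    """
    a, b, c, d = calls
    for v in (a, b, c, d):
        if v not in (0, 1, 2):
            raise ValueError(f"genotype call {v!r} outside {{2,1,0}}")
    return 27 * a + 9 * b + 3 * c + d


def class_label(idx: int) -> str:
    """Digit label of a genotype class, e.g. 80 -> '2222'."""
    a, r = divmod(idx, 27)
    b, r = divmod(r, 9)
    c, d = divmod(r, 3)
    return f"{a}{b}{c}{d}"


CLASS_LABELS = tuple(class_label(i) for i in range(N_CLASSES))

#: class index of every ordered (maternal, paternal) haplotype pair
PAIR_CLASS = np.array(
    [
        [classify_offspring(haplotype_calls(hm, hp)) for hp in range(N_HAPLOTYPES)]
        for hm in range(N_HAPLOTYPES)
    ]
)


def _as_gamete_vector(g) -> np.ndarray:
    g = np.asarray(g, dtype=float)
    if g.shape != (N_TYPES,):
        raise ValueError(f"expected 8 gamete-type frequencies, got shape {g.shape}")
    if not np.all(np.isfinite(g)):
        raise ValueError("gamete frequencies must be finite")
    if np.any(g < -1e-9):
        t = int(np.argmin(g))
        raise ValueError(f"gamete frequency {TYPE_LABELS[t]} is negative ({g[t]:.3g})")
    if abs(g.sum() - 1.0) > 1e-9:
        raise ValueError(f"gamete frequencies sum to {g.sum():.12g}, expected 1")
    return np.clip(g, 0.0, None)


@dataclass(frozen=True)
class GameteFrequencies:
    """The eight gamete-type probabilities g000..g111.

    Index ``t`` packs the interval crossover indicators (i_AB, i_BC, i_CD)
    in binary, so ``g[4]`` is g100, the frequency of gametes recombinant in
    A-B only.  Entries are non-negative and sum to one.
    """

    g: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "g", _as_gamete_vector(self.g))

    def __getitem__(self, t: int) -> float:
        return float(self.g[t])

    @property
    def as_dict(self) -> dict[str, float]:
        return {lab: float(v) for lab, v in zip(TYPE_LABELS, self.g)}

    def haplotype_probs(self) -> np.ndarray:
        """Probabilities of the 16 concrete gametes: each type splits g_t/2
        over its complementary pair (meiotic symmetry)."""
        return self.g[HAPLOTYPE_TYPE] / 2.0


@dataclass(frozen=True)
class RecombinationProfile:
    """The six pairwise recombination fractions of a four-marker window."""

    r_ab: float
    r_bc: float
    r_cd: float
    r_ac: float
    r_bd: float
    r_ad: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.r_ab, self.r_bc, self.r_cd, self.r_ac, self.r_bd, self.r_ad]
        )

    FIELDS = ("r_ab", "r_bc", "r_cd", "r_ac", "r_bd", "r_ad")


@dataclass(frozen=True)
class CoCProfile:
    """Coincidence coefficients for a four-marker window.

    C1 pairs intervals A-B x B-C, C2 pairs B-C x C-D, C3 pairs the disjoint
    A-B x C-D, and C4 is the triple-interval ("high-dimensional") coefficient
    A-B x B-C x C-D.  A coefficient whose denominator (product of interval
    recombination fractions) is zero is 0.0 when its numerator is also zero
    and NaN ("undefined") when the numerator is positive; NaN entries are
    excluded from downstream summaries.
    """

    c1: float
    c2: float
    c3: float
    c4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4])

    def defined(self) -> np.ndarray:
        return np.isfinite(self.as_array())

    FIELDS = ("c1", "c2", "c3", "c4")


# gamete types entering each pairwise recombination fraction: a gamete is
# recombinant between two markers iff the XOR of the crossover indicators of
# the intervals between them is 1
_R_TYPES = {
    "r_ab": (4, 5, 6, 7),   # i_AB = 1
    "r_bc": (2, 3, 6, 7),   # i_BC = 1
    "r_cd": (1, 3, 5, 7),   # i_CD = 1
    "r_ac": (2, 3, 4, 5),   # i_AB xor i_BC = 1
    "r_bd": (1, 2, 5, 6),   # i_BC xor i_CD = 1
    "r_ad": (1, 2, 4, 7),   # i_AB xor i_BC xor i_CD = 1
}


def recombination_fractions(g: GameteFrequencies | np.ndarray) -> RecombinationProfile:
    """Pairwise recombination fractions from gamete-type frequencies.

    Each fraction is the total frequency of the four gamete types that are
    recombinant between the marker pair, e.g.
    r_AB = g111 + g110 + g101 + g100 and r_AD = g111 + g010 + g100 + g001.
    """
    if not isinstance(g, GameteFrequencies):
        g = GameteFrequencies(g)
    vals = {name: float(g.g[list(t)].sum()) for name, t in _R_TYPES.items()}
    return RecombinationProfile(**vals)


def _coc_ratio(num: float, den: float) -> float:
    if den > 0.0:
        return num / den
    return 0.0 if num <= 0.0 else float("nan")


def coincidence_coefficients(
    g: GameteFrequencies | np.ndarray,
    r: RecombinationProfile | None = None,
) -> CoCProfile:
    """Coincidence coefficients C1..C4 from gamete-type frequencies.

    C4 = g111 / (r_AB r_BC r_CD); C1 = (g111+g110)/(r_AB r_BC);
    C2 = (g111+g011)/(r_BC r_CD); C3 = (g111+g101)/(r_AB r_CD).
    A value of 1 indicates independence of crossovers between the intervals,
    values below 1 positive interference, values above 1 negative
    interference.  If ``r`` is given it must agree with the fractions implied
    by ``g`` to 1e-9.
    """
    if not isinstance(g, GameteFrequencies):
        g = GameteFrequencies(g)
    r_own = recombination_fractions(g)
    if r is not None:
        if np.max(np.abs(r.as_array() - r_own.as_array())) > 1e-9:
            raise ValueError("recombination profile inconsistent with gamete frequencies")
    r = r_own
    g111, g110, g011, g101 = g[7], g[6], g[3], g[5]
    return CoCProfile(
        c1=_coc_ratio(g111 + g110, r.r_ab * r.r_bc),
        c2=_coc_ratio(g111 + g011, r.r_bc * r.r_cd),
        c3=_coc_ratio(g111 + g101, r.r_ab * r.r_cd),
        c4=_coc_ratio(g111, r.r_ab * r.r_bc * r.r_cd),
    )


def independence_gametes(r_ab: float, r_bc: float, r_cd: float) -> GameteFrequencies:
    """Gamete-type frequencies under no interference.

    With independent crossovers per interval, g_{ijk} is the product over
    the three intervals of r (if the indicator is 1) or 1-r; all four
    coincidence coefficients then equal 1.
    """
    for name, r in (("r_ab", r_ab), ("r_bc", r_bc), ("r_cd", r_cd)):
        if not 0.0 <= r <= 0.5:
            raise ValueError(f"{name}={r} outside [0, 0.5]")
    g = np.empty(N_TYPES)
    for t in range(N_TYPES):
        i_ab, i_bc, i_cd = (t >> 2) & 1, (t >> 1) & 1, t & 1
        g[t] = (
            (r_ab if i_ab else 1 - r_ab)
            * (r_bc if i_bc else 1 - r_bc)
            * (r_cd if i_cd else 1 - r_cd)
        )
    return GameteFrequencies(g)


def pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sparse mixture structure of the 81-class genotype table.

    Returns arrays (cls, tm, tp, mult): component ``k`` contributes
    ``mult[k] * g_m[tm[k]] * g_p[tp[k]] / 4`` to class ``cls[k]``, where
    ``mult`` counts the ordered haplotype pairs of that type pair falling in
    the class.  This is the E-step backbone of the EM estimator.
    """
    return _CLS, _TM, _TP, _MULT


def _build_pair_structure():
    acc: dict[tuple[int, int, int], int] = {}
    for hm in range(N_HAPLOTYPES):
        tm = HAPLOTYPE_TYPE[hm]
        for hp in range(N_HAPLOTYPES):
            key = (int(PAIR_CLASS[hm, hp]), int(tm), int(HAPLOTYPE_TYPE[hp]))
            acc[key] = acc.get(key, 0) + 1
    keys = sorted(acc)
    cls = np.array([k[0] for k in keys])
    tm = np.array([k[1] for k in keys])
    tp = np.array([k[2] for k in keys])
    mult = np.array([acc[k] for k in keys], dtype=float)
    return cls, tm, tp, mult


_CLS, _TM, _TP, _MULT = _build_pair_structure()


@dataclass(frozen=True)
class GenotypeClassTable:
    """Expected frequencies of the 81 identifiable four-marker genotype
    classes of a full-sib F2, as a mixture of parental gamete-type products.

    ``freq[c]`` is the probability of class ``c`` (see
    :func:`classify_offspring` for the indexing); ``components(c)`` lists the
    (maternal type, paternal type, coefficient) triples composing it, with
    coefficient = multiplicity / 4 from splitting each type over its two
    complementary haplotypes.
    """

    freq: np.ndarray
    g_maternal: GameteFrequencies = field(repr=False)
    g_paternal: GameteFrequencies = field(repr=False)

    def components(self, cls_idx: int) -> list[tuple[int, int, float]]:
        mask = _CLS == cls_idx
        return [
            (int(tm), int(tp), float(m) / 4.0)
            for tm, tp, m in zip(_TM[mask], _TP[mask], _MULT[mask])
        ]


def genotype_class_table(
    g_maternal: GameteFrequencies | np.ndarray,
    g_paternal: GameteFrequencies | np.ndarray | None = None,
) -> GenotypeClassTable:
    """Exact 81-class genotype distribution from parental gamete frequencies.

    Built by exhaustive enumeration: each parent's 8 types expand to 16
    haplotypes at g_t/2 each, the 16x16 ordered pairs are mapped to their
    {2,1,0}^4 genotype class, and probability accumulates per class.  With
    ``g_paternal`` omitted both parents share ``g_maternal`` (the symmetric
    full-sib default).
    """
    if not isinstance(g_maternal, GameteFrequencies):
        g_maternal = GameteFrequencies(g_maternal)
    if g_paternal is None:
        g_paternal = g_maternal
    elif not isinstance(g_paternal, GameteFrequencies):
        g_paternal = GameteFrequencies(g_paternal)
    w = _MULT * g_maternal.g[_TM] * g_paternal.g[_TP] / 4.0
    freq = np.bincount(_CLS, weights=w, minlength=N_CLASSES)
    return GenotypeClassTable(freq=freq, g_maternal=g_maternal, g_paternal=g_paternal)
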