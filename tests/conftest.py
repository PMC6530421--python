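import numpy as np
import pandas as pd
import pytest

from fourpoint.core import GameteFrequencies
from fourpoint.io import GeneticMap, GenotypeMatrix


def random_gametes(rng: np.random.Generator, alpha: float = 1.0) -> GameteFrequencies:
    """A random valid gamete-type frequency vector (Dirichlet)."""
    return GameteFrequencies(rng.dirichlet(np.full(8, alpha)))


@pytest.fixture
def rng():
    return np.random.default_rng(20190515)


@pytest.fixture
def small_map():
    """One linkage group, 4 hk_hk markers at 0,1,2,3 cM."""
    return GeneticMap(
        pd.DataFrame(
            {
                "name": ["m1", "m2", "m3", "m4"],
                "linkage_group": ["1"] * 4,
                "position_cM": [0.0, 1.0, 2.0, 3.0],
                "seg_type": ["hk_hk"] * 4,
            }
        )
    )


def matrix_from_rows(rows, markers=("m1", "m2", "m3", "m4")):
    """Build a GenotypeMatrix from a list of per-individual call tuples
    (None = missing)."""
    data = np.array(
        [[np.nan if v is None else float(v) for v in row] for row in rows]
    )
    return GenotypeMatrix(
        pd.DataFrame(
            data,
            index=pd.Index([f"i{k}" for k in range(len(rows))], name="id"),
            columns=list(markers),
        )
    )


# ---------------------------------------------------------------------------
# independent brute-force oracles (deliberately naive, dictionary-based)
# ---------------------------------------------------------------------------

def enumerate_haplotypes(g: GameteFrequencies):
    """The 16 concrete gametes as (allele tuple, probability), built from
    first principles: walk the 8 indicator triples, reconstruct the two
    complementary allele strings, give each half the type frequency."""
    out = []
    for t in range(8):
        i_ab, i_bc, i_cd = (t >> 2) & 1, (t >> 1) & 1, t & 1
        a = 1
        b = a ^ i_ab
        c = b ^ i_bc
        d = c ^ i_cd
        hap = (a, b, c, d)
        comp = tuple(1 - x for x in hap)
        out.append((hap, g[t] / 2.0))
        out.append((comp, g[t] / 2.0))
    return out


def brute_force_recombination(g: GameteFrequencies) -> dict:
    """Pairwise recombination fractions by counting allele mismatches over
    the explicit 16-gamete enumeration."""
    pairs = {"r_ab": (0, 1), "r_bc": (1, 2), "r_cd": (2, 3),
             "r_ac": (0, 2), "r_bd": (1, 3), "r_ad": (0, 3)}
    out = {}
    for name, (i, j) in pairs.items():
        out[name] = sum(p for hap, p in enumerate_haplotypes(g) if hap[i] != hap[j])
    return out


def brute_force_coc(g: GameteFrequencies) -> dict:
    """Coincidence coefficients as observed multi-recombinant mass over the
    independence expectation, classifying each gamete by its crossover
    pattern."""
    r = brute_force_recombination(g)
    mass = {"c1": 0.0, "c2": 0.0, "c3": 0.0, "c4": 0.0}
    for hap, p in enumerate_haplotypes(g):
        a, b, c, d = hap
        x_ab, x_bc, x_cd = a != b, b != c, c != d
        if x_ab and x_bc:
            mass["c1"] += p
        if x_bc and x_cd:
            mass["c2"] += p
        if x_ab and x_cd:
            mass["c3"] += p
        if x_ab and x_bc and x_cd:
            mass["c4"] += p
    den = {
        "c1": r["r_ab"] * r["r_bc"],
        "c2": r["r_bc"] * r["r_cd"],
        "c3": r["r_ab"] * r["r_cd"],
        "c4": r["r_ab"] * r["r_bc"] * r["r_cd"],
    }
    out = {}
    for k in mass:
        if den[k] > 0:
            out[k] = mass[k] / den[k]
        else:
            out[k] = 0.0 if mass[k] == 0 else float("nan")
    return out


def brute_force_class_table(g_m: GameteFrequencies, g_p: GameteFrequencies) -> dict:
    """81-class genotype distribution by literal 16x16 ordered-pair
    enumeration accumulated into a dictionary keyed by call strings."""
    table: dict[str, float] = {}
    for hm, pm in enumerate_haplotypes(g_m):
        for hp, pp in enumerate_haplotypes(g_p):
            label = "".join(str(x + y) for x, y in zip(hm, hp))
            table[label] = table.get(label, 0.0) + pm * pp
    return table
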