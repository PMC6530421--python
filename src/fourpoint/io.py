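"""Readers and writers for the package's TSV/JSON dialects.

Three tabular formats are fixed here: the genetic map (marker, linkage
group, cM position, segregation type), the offspring genotype matrix
(individuals x markers, codes 2/1/0 counting parental-phase alleles, with
NA/-/empty as missing), and the per-window scan table whose leading columns
mirror the r_AB..C4 landscape layout.  All writers prepend ``#`` comment
headers (version, seed, config hash) and all readers skip them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CoCProfile, RecombinationProfile

SEG_TYPES = ("hk_hk", "lm_ll", "nn_np")
MISSING_TOKENS = ("NA", "-", "")

#: leading scan-table columns, in landscape-table order
SCAN_COLUMNS = [
    "r_AB", "r_BC", "r_CD", "r_AC", "r_BD", "r_AD",
    "C1", "C2", "C3", "C4",
    "lg", "marker1", "marker2", "marker3", "marker4",
]
#: trailing provenance columns needed to re-load a scan for regional analysis
SCAN_EXTRA_COLUMNS = ["method", "n_used", "pos1", "pos2", "pos3", "pos4"]


class FormatError(ValueError):
    """Raised when an input file violates the dialect, with row/field context."""


@dataclass(frozen=True)
class GeneticMap:
    """An ordered genetic map: unique marker names with linkage group,
    centimorgan position and segregation type (hk_hk: both parents
    heterozygous; lm_ll: maternal testcross; nn_np: paternal testcross)."""

    markers: pd.DataFrame = field(repr=False)  # name, linkage_group, position_cM, seg_type

    def __post_init__(self):
        df = self.markers.reset_index(drop=True)
        errors = []
        dup = df["name"][df["name"].duplicated()]
        if len(dup):
            errors.append(f"duplicate marker name(s): {sorted(set(dup))}")
        bad_seg = df.loc[~df["seg_type"].isin(SEG_TYPES)]
        for i, row in bad_seg.iterrows():
            errors.append(f"row {i}: unknown seg_type {row['seg_type']!r}")
        if not np.isfinite(df["position_cM"]).all():
            errors.append("non-finite positions present")
        if errors:
            raise FormatError("; ".join(errors))
        df = df.sort_values(
            ["linkage_group", "position_cM", "name"], kind="stable"
        ).reset_index(drop=True)
        object.__setattr__(self, "markers", df)

    @property
    def names(self) -> list[str]:
        return list(self.markers["name"])

    def linkage_groups(self) -> list[str]:
        return list(dict.fromkeys(self.markers["linkage_group"]))

    def markers_of(self, lg: str) -> pd.DataFrame:
        sub = self.markers[self.markers["linkage_group"] == str(lg)]
        if sub.empty:
            raise KeyError(f"linkage group {lg!r} not in map")
        return sub.reset_index(drop=True)

    def position(self, name: str) -> float:
        row = self.markers.loc[self.markers["name"] == name]
        if row.empty:
            raise KeyError(f"marker {name!r} not in map")
        return float(row["position_cM"].iloc[0])

    def seg_type(self, name: str) -> str:
        row = self.markers.loc[self.markers["name"] == name]
        if row.empty:
            raise KeyError(f"marker {name!r} not in map")
        return str(row["seg_type"].iloc[0])

    def span(self, lg: str) -> tuple[float, float]:
        pos = self.markers_of(lg)["position_cM"]
        return float(pos.min()), float(pos.max())


@dataclass(frozen=True)
class GenotypeMatrix:
    """Offspring genotype calls, individuals x markers.

    Calls are floats with values 2/1/0 (count of parental-phase alleles) or
    NaN for missing; the column set must match the accompanying map.
    """

    calls: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.calls
        vals = df.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise FormatError(
                f"call {vals[i, j]!r} at individual {df.index[i]!r}, "
                f"marker {df.columns[j]!r} outside {{2,1,0,missing}}"
            )

    @property
    def individuals(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_individuals(self) -> int:
        return len(self.calls)

    def window(self, markers) -> np.ndarray:
        """Calls for an ordered marker quadruple, shape (n, 4), NaN=missing."""
        missing = [m for m in markers if m not in self.calls.columns]
        if missing:
            raise KeyError(f"marker(s) not in matrix: {missing}")
        return self.calls.loc[:, list(markers)].to_numpy(dtype=float)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_genetic_map(path) -> GeneticMap:
    """Read a genetic-map TSV with columns name, linkage_group, position_cM,
    seg_type; markers come back sorted by (linkage group, position, name)."""
    df = _read_tsv(path)
    required = ["name", "linkage_group", "position_cM", "seg_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"map file missing column(s) {missing}")
    errors = []
    pos = pd.to_numeric(df["position_cM"], errors="coerce")
    for i in np.flatnonzero(pos.isna()):
        errors.append(f"row {i}: non-numeric position_cM {df['position_cM'].iloc[i]!r}")
    if errors:
        raise FormatError("; ".join(errors))
    out = pd.DataFrame(
        {
            "name": df["name"],
            "linkage_group": df["linkage_group"],
            "position_cM": pos.astype(float),
            "seg_type": df["seg_type"],
        }
    )
    return GeneticMap(out)


def write_genetic_map(gmap: GeneticMap, path, header: str | None = None) -> None:
    _write_with_header(gmap.markers, path, header)


def read_genotype_matrix(path, gmap: GeneticMap | None = None) -> GenotypeMatrix:
    """Read a genotype TSV: first column individual id, remaining columns
    marker names; cells in {2,1,0} or a missing token (NA, -, empty)."""
    df = _read_tsv(path)
    id_col = df.columns[0]
    marker_cols = list(df.columns[1:])
    if gmap is not None:
        unknown = [m for m in marker_cols if m not in set(gmap.names)]
        if unknown:
            raise FormatError(f"genotype column(s) not in map: {unknown}")
    data = {}
    for col in marker_cols:
        raw = df[col].str.strip()
        vals = np.full(len(raw), np.nan)
        for i, tok in enumerate(raw):
            if tok in MISSING_TOKENS:
                continue
            if tok not in ("0", "1", "2"):
                raise FormatError(
                    f"row {i} (individual {df[id_col].iloc[i]!r}), column {col!r}: "
                    f"call {tok!r} outside code set"
                )
            vals[i] = float(tok)
        data[col] = vals
    out = pd.DataFrame(data, index=pd.Index(df[id_col], name=id_col))
    return GenotypeMatrix(out)


def write_genotype_matrix(matrix: GenotypeMatrix, path, header: str | None = None) -> None:
    df = matrix.calls.copy()
    # integers where present, NA for missing
    df = df.map(lambda v: "NA" if math.isnan(v) else str(int(v)))
    _write_with_header(df, path, header, index=True)


def _fmt(v: float | None) -> str:
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return "NA"
    return repr(float(v))


def scan_to_frame(records) -> pd.DataFrame:
    """Flatten scan records into the landscape-table layout plus provenance
    columns (method, n_used, window positions)."""
    rows = []
    for rec in records:
        r = rec.r.as_array() if rec.r is not None else np.full(6, np.nan)
        c = rec.coc.as_array() if rec.coc is not None else np.full(4, np.nan)
        row = dict(zip(SCAN_COLUMNS[:6], r))
        row.update(zip(SCAN_COLUMNS[6:10], c))
        row["lg"] = rec.lg
        for k in range(4):
            row[f"marker{k + 1}"] = rec.markers[k]
            row[f"pos{k + 1}"] = rec.positions[k]
        row["method"] = rec.method
        row["n_used"] = rec.n_used
        rows.append(row)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS + SCAN_EXTRA_COLUMNS)


def write_scan_table(records, path, header: str | None = None) -> None:
    """Write scan records as a TSV whose first 15 columns follow the
    landscape-table order r_AB..r_AD, C1..C4, lg, marker1..marker4."""
    df = scan_to_frame(records)
    for col in SCAN_COLUMNS[:10] + SCAN_EXTRA_COLUMNS[2:]:
        df[col] = df[col].map(_fmt)
    _write_with_header(df, path, header)


def read_scan_table(path) -> list["ScanRecord"]:
    from .scan import ScanRecord  # local import to avoid cycle

    df = _read_tsv(path)
    records = []
    for _, row in df.iterrows():
        def num(col):
            return float("nan") if row[col] == "NA" else float(row[col])

        method = row.get("method", "em")
        if method == "skipped":
            r = coc = None
        else:
            r = RecombinationProfile(*(num(c) for c in SCAN_COLUMNS[:6]))
            coc = CoCProfile(*(num(c) for c in SCAN_COLUMNS[6:10]))
        records.append(
            ScanRecord(
                lg=str(row["lg"]),
                markers=tuple(row[f"marker{k + 1}"] for k in range(4)),
                positions=tuple(num(f"pos{k + 1}") for k in range(4)),
                r=r,
                coc=coc,
                method=method,
                n_used=int(float(row["n_used"])) if row["n_used"] != "NA" else 0,
            )
        )
    return records


def _write_with_header(df: pd.DataFrame, path, header: str | None, index: bool = False):
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_truth(truth, path) -> None:
    """Serialize a :class:`fourpoint.simulate.SimulationTruth` to JSON
    (NaN-free: undefined coefficients become null)."""

    def clean(x):
        if isinstance(x, float) and math.isnan(x):
            return None
        return x

    payload = {
        "seed": truth.seed,
        "n": truth.n,
        "windows": [
            {
                "lg": w["lg"],
                "markers": list(w["markers"]),
                "positions": [float(p) for p in w["positions"]],
                "seg_type": w["seg_type"],
                "g": [float(v) for v in w["g"]],
                "r": [float(v) for v in w["r"]],
                "C": [clean(float(v)) for v in w["C"]],
            }
            for w in truth.windows
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path):
    from .simulate import SimulationTruth

    payload = json.loads(Path(path).read_text())
    windows = []
    for w in payload["windows"]:
        w = dict(w)
        w["C"] = [float("nan") if v is None else v for v in w["C"]]
        windows.append(w)
    return SimulationTruth(
        windows=windows, seed=payload["seed"], n=payload["n"]
    )
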