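"""Core data containers and table I/O for pollen calibration datasets.

A modern calibration set couples a samples x taxa pollen table with
per-sample site metadata (coordinates, mean annual temperature and
precipitation, and the Human Influence Index).  A fossil record couples a
pollen table with a depth/age axis.  All tables travel as delimited text
(comma or tab, sniffed on read); pollen values are either raw counts or
percentages closed to 100 per sample.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PollenMatrix",
    "SiteMeta",
    "ModernDataset",
    "FossilRecord",
    "SchemaError",
    "read_table",
    "write_table",
    "to_percentages",
    "harmonize_taxa",
]

HII_MIN, HII_MAX = 0.0, 64.0

META_REQUIRED = ["sample_id", "lon", "lat", "mat_c", "map_mm", "hii"]
META_OPTIONAL = ["elev", "veg_label"]


class SchemaError(ValueError):
    """A table does not conform to the expected schema or invariants."""


@dataclass(frozen=True)
class PollenMatrix:
    """A samples x taxa abundance table.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, in row order.
    taxa : sequence of str
        Unique taxon names, in column order.
    values : ndarray of shape (n_samples, n_taxa)
        Nonnegative counts or percentages; no missing cells.
    basis : {"counts", "percentages"}
        Unit of ``values``.  Percentage rows sum to 100 within 1e-6.
    """

    sample_ids: tuple
    taxa: tuple
    values: np.ndarray
    basis: str = "counts"
    #: taxa forming the pollen sum when basis="percentages"; None means all.
    sum_taxa: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "taxa", tuple(str(t) for t in self.taxa))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.sample_ids), len(self.taxa)):
            raise SchemaError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxa)} taxa"
            )
        if not np.isfinite(vals).all():
            raise SchemaError("pollen values contain missing or non-finite cells")
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise SchemaError(
                f"negative pollen value at sample {self.sample_ids[bad[0]]!r}, "
                f"taxon {self.taxa[bad[1]]!r}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise SchemaError("duplicate sample_ids in pollen matrix")
        if len(set(self.taxa)) != len(self.taxa):
            raise SchemaError("duplicate taxon names in pollen matrix")
        if self.basis not in ("counts", "percentages"):
            raise SchemaError(f"unknown basis {self.basis!r}")
        if self.sum_taxa is not None:
            object.__setattr__(self, "sum_taxa", tuple(self.sum_taxa))
            if not set(self.sum_taxa) <= set(self.taxa):
                raise SchemaError("sum_taxa must be a subset of taxa")
        if self.basis == "percentages":
            if self.sum_taxa is None:
                sums = vals.sum(axis=1)
            else:
                cols = [i for i, t in enumerate(self.taxa) if t in set(self.sum_taxa)]
                sums = vals[:, cols].sum(axis=1)
            if not np.allclose(sums, 100.0, atol=1e-6):
                bad = np.argmin(np.isclose(sums, 100.0, atol=1e-6))
                raise SchemaError(
                    f"percentage row {self.sample_ids[bad]!r} sums to {sums[bad]!r}, not 100"
                )
        object.__setattr__(self, "values", vals)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids), columns=list(self.taxa))

    def select_samples(self, mask_or_idx) -> "PollenMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return PollenMatrix(
            tuple(self.sample_ids[i] for i in idx),
            self.taxa,
            self.values[idx],
            self.basis,
            self.sum_taxa,
        )


@dataclass(frozen=True)
class SiteMeta:
    """Per-sample site metadata: coordinates, climate, and HII."""

    sample_ids: tuple
    lon: np.ndarray
    lat: np.ndarray
    mat: np.ndarray  # mean annual temperature, degrees C
    map_: np.ndarray  # mean annual precipitation, mm
    hii: np.ndarray  # Human Influence Index, 0-64
    elev: np.ndarray | None = None
    veg_label: tuple | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise SchemaError("duplicate sample_ids in site metadata")
        for name in ("lon", "lat", "mat", "map_", "hii"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise SchemaError(f"{name} length {arr.shape} != {n} samples")
            if not np.isfinite(arr).all():
                raise SchemaError(f"non-finite values in {name}")
            object.__setattr__(self, name, arr)
        if ((self.lon < -180) | (self.lon > 180)).any():
            raise SchemaError("longitude outside [-180, 180]")
        if ((self.lat < -90) | (self.lat > 90)).any():
            raise SchemaError("latitude outside [-90, 90]")
        if (self.map_ < 0).any():
            raise SchemaError("negative mean annual precipitation")
        if ((self.hii < HII_MIN) | (self.hii > HII_MAX)).any():
            bad = self.sample_ids[int(np.argmax((self.hii < HII_MIN) | (self.hii > HII_MAX)))]
            raise SchemaError(f"HII outside [0, 64] for sample {bad!r}")
        if self.elev is not None:
            object.__setattr__(self, "elev", np.asarray(self.elev, dtype=float))
        if self.veg_label is not None:
            object.__setattr__(self, "veg_label", tuple(self.veg_label))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def variable(self, name: str) -> np.ndarray:
        """Return the climate variable array for ``name`` in {"mat", "map"}."""
        if name == "mat":
            return self.mat
        if name == "map":
            return self.map_
        raise KeyError(f"unknown climate variable {name!r} (expected 'mat' or 'map')")

    def select_samples(self, mask_or_idx) -> "SiteMeta":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SiteMeta(
            tuple(self.sample_ids[i] for i in idx),
            self.lon[idx], self.lat[idx], self.mat[idx], self.map_[idx], self.hii[idx],
            None if self.elev is None else self.elev[idx],
            None if self.veg_label is None else tuple(self.veg_label[i] for i in idx),
        )

    def to_frame(self) -> pd.DataFrame:
        d = {
            "sample_id": list(self.sample_ids),
            "lon": self.lon, "lat": self.lat,
            "mat_c": self.mat, "map_mm": self.map_, "hii": self.hii,
        }
        if self.elev is not None:
            d["elev"] = self.elev
        if self.veg_label is not None:
            d["veg_label"] = list(self.veg_label)
        return pd.DataFrame(d)


@dataclass(frozen=True)
class ModernDataset:
    """An aligned modern pollen matrix plus site metadata: the calibration universe."""

    pollen: PollenMatrix
    meta: SiteMeta

    def __post_init__(self):
        if self.pollen.sample_ids != self.meta.sample_ids:
            raise SchemaError("pollen and metadata sample_ids are not aligned one-to-one")

    @property
    def n_samples(self) -> int:
        return self.pollen.n_samples

    def select_samples(self, mask_or_idx) -> "ModernDataset":
        return ModernDataset(
            self.pollen.select_samples(mask_or_idx),
            self.meta.select_samples(mask_or_idx),
        )


@dataclass(frozen=True)
class FossilRecord:
    """A fossil pollen table with a strictly increasing depth axis and ages."""

    pollen: PollenMatrix
    depth: np.ndarray  # cm
    age: np.ndarray  # cal yr BP

    def __post_init__(self):
        depth = np.asarray(self.depth, dtype=float)
        age = np.asarray(self.age, dtype=float)
        n = self.pollen.n_samples
        if depth.shape != (n,) or age.shape != (n,):
            raise SchemaError("depth/age length does not match pollen samples")
        if not np.isfinite(depth).all() or not np.isfinite(age).all():
            raise SchemaError("non-finite depth or age")
        if not (np.diff(depth) > 0).all():
            raise SchemaError("depth must be strictly increasing")
        if not (np.diff(age) >= 0).all():
            raise SchemaError("age must be nondecreasing with depth")
        object.__setattr__(self, "depth", depth)
        object.__setattr__(self, "age", age)

    @property
    def n_samples(self) -> int:
        return self.pollen.n_samples


def _read_frame(path) -> pd.DataFrame:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        head = fh.read(8192)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(head, delimiters=",\t")
            sep = dialect.delimiter
        except csv.Error:
            sep = "\t" if "\t" in head.splitlines()[0] else ","
        return pd.read_csv(fh, sep=sep)


def _numeric_block(df: pd.DataFrame, cols, path) -> np.ndarray:
    block = df[cols].apply(pd.to_numeric, errors="coerce")
    if block.isna().any().any():
        r, c = np.argwhere(block.isna().to_numpy())[0]
        raise SchemaError(
            f"{path}: non-numeric cell at row {r + 2} (1-based incl. header), column {cols[c]!r}"
        )
    return block.to_numpy(dtype=float)


def read_table(path, schema: str):
    """Read a delimited text table into a typed, validated object.

    ``schema`` selects the expected layout: ``"pollen"`` (sample id then
    taxon columns), ``"meta"`` (sample_id, lon, lat, [elev], mat_c, map_mm,
    hii, [veg_label]) or ``"fossil"`` (sample_id, depth_cm, age_calbp, then
    taxon columns).
    """
    df = _read_frame(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: expected at least two columns")
    if schema == "pollen":
        ids = df.iloc[:, 0].astype(str)
        taxa = list(df.columns[1:])
        vals = _numeric_block(df, taxa, path)
        basis = "percentages" if np.allclose(vals.sum(axis=1), 100.0, atol=1e-6) else "counts"
        return PollenMatrix(tuple(ids), tuple(taxa), vals, basis)
    if schema == "meta":
        missing = [c for c in META_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required metadata column(s) {missing}")
        num = _numeric_block(df, ["lon", "lat", "mat_c", "map_mm", "hii"], path)
        elev = None
        if "elev" in df.columns:
            elev = _numeric_block(df, ["elev"], path)[:, 0]
        veg = tuple(df["veg_label"].astype(str)) if "veg_label" in df.columns else None
        return SiteMeta(
            tuple(df["sample_id"].astype(str)),
            num[:, 0], num[:, 1], num[:, 2], num[:, 3], num[:, 4],
            elev, veg,
        )
    if schema == "fossil":
        for col in ("sample_id", "depth_cm", "age_calbp"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required fossil column {col!r}")
        taxa = [c for c in df.columns if c not in ("sample_id", "depth_cm", "age_calbp")]
        if not taxa:
            raise SchemaError(f"{path}: fossil table has no taxon columns")
        vals = _numeric_block(df, taxa, path)
        axes = _numeric_block(df, ["depth_cm", "age_calbp"], path)
        basis = "percentages" if np.allclose(vals.sum(axis=1), 100.0, atol=1e-6) else "counts"
        pm = PollenMatrix(tuple(df["sample_id"].astype(str)), tuple(taxa), vals, basis)
        return FossilRecord(pm, axes[:, 0], axes[:, 1])
    raise ValueError(f"unknown schema {schema!r} (expected pollen|meta|fossil)")


def write_table(obj, path, sep: str = "\t") -> None:
    """Write a typed object back to delimited text at full precision."""
    if isinstance(obj, PollenMatrix):
        df = obj.to_frame().reset_index(names="sample_id")
    elif isinstance(obj, SiteMeta):
        df = obj.to_frame()
    elif isinstance(obj, FossilRecord):
        df = obj.pollen.to_frame().reset_index(names="sample_id")
        df.insert(1, "depth_cm", obj.depth)
        df.insert(2, "age_calbp", obj.age)
    elif isinstance(obj, pd.DataFrame):
        df = obj
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def to_percentages(pm: PollenMatrix, sum_taxa=None) -> PollenMatrix:
    """Convert counts to percentages of the pollen sum.

    The pollen sum defaults to all taxa; ``sum_taxa`` restricts it to a
    subset (taxa outside the sum are still reported as percent of that sum,
    so rows sum to 100 over the sum taxa only in that case).  Idempotent on
    percentage input when no subset is given.
    """
    if pm.basis == "percentages":
        if sum_taxa is not None:
            raise ValueError("cannot re-close percentages to a taxon subset")
        return pm
    if sum_taxa is None:
        sums = pm.values.sum(axis=1)
    else:
        sum_taxa = set(sum_taxa)
        unknown = sum_taxa - set(pm.taxa)
        if unknown:
            raise KeyError(f"sum_taxa not in matrix: {sorted(unknown)}")
        cols = [i for i, t in enumerate(pm.taxa) if t in sum_taxa]
        sums = pm.values[:, cols].sum(axis=1)
    zero = sums <= 0
    if zero.any():
        bad = [pm.sample_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"zero pollen sum for sample(s): {bad}")
    pct = 100.0 * pm.values / sums[:, None]
    st = None if sum_taxa is None else tuple(t for t in pm.taxa if t in sum_taxa)
    return PollenMatrix(pm.sample_ids, pm.taxa, pct, "percentages", st)


def _canon(name: str) -> str:
    return name.strip().casefold()


def harmonize_taxa(modern: PollenMatrix, fossil: PollenMatrix):
    """Restrict two percentage matrices to their shared taxa and re-close rows.

    Taxon matching is exact-string after trimming and case-folding.  Returns
    the two harmonized matrices and a report dict listing the taxa dropped
    from each side and the percentage mass dropped per sample.
    """
    for pm, name in ((modern, "modern"), (fossil, "fossil")):
        if pm.basis != "percentages":
            raise ValueError(f"{name} matrix must be in percentages (run to_percentages first)")
    m_canon = {_canon(t): i for i, t in enumerate(modern.taxa)}
    f_canon = {_canon(t): i for i, t in enumerate(fossil.taxa)}
    shared = [c for c in m_canon if c in f_canon]
    if not shared:
        raise ValueError("no taxa shared between modern and fossil matrices")
    m_idx = [m_canon[c] for c in shared]
    f_idx = [f_canon[c] for c in shared]

    def _restrict(pm: PollenMatrix, idx):
        sub = pm.values[:, idx]
        sums = sub.sum(axis=1)
        zero = sums <= 0
        if zero.any():
            bad = [pm.sample_ids[i] for i in np.flatnonzero(zero)]
            raise ValueError(f"sample(s) lose all pollen mass under harmonization: {bad}")
        closed = 100.0 * sub / sums[:, None]
        taxa = tuple(pm.taxa[i] for i in idx)
        return PollenMatrix(pm.sample_ids, taxa, closed, "percentages"), 100.0 - sums

    m_out, m_dropped_mass = _restrict(modern, m_idx)
    f_out, f_dropped_mass = _restrict(fossil, f_idx)
    report = {
        "shared_taxa": list(m_out.taxa),
        "dropped_modern": [t for t in modern.taxa if _canon(t) not in f_canon],
        "dropped_fossil": [t for t in fossil.taxa if _canon(t) not in m_canon],
        "dropped_mass_modern": dict(zip(modern.sample_ids, m_dropped_mass)),
        "dropped_mass_fossil": dict(zip(fossil.sample_ids, f_dropped_mass)),
    }
    return m_out, f_out, report
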