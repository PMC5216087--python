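"""Feature-matrix container, TSV/CSV I/O, m/z binning and feature naming.

The central object is :class:`FeatureMatrix`: a samples x features intensity
table where every feature carries an accurate m/z and a retention time.
On disk the matrix is a plain TSV/CSV with one row per feature (columns
``name``, ``mz``, ``rt``, then one intensity column per sample), the layout
produced by peak pickers after XCMS-style processing.

Binning pools accurate-mass features into fixed-width m/z windows (default
0.01) so that profiles from different runs can be compared column-by-column;
the un-binned accurate masses are retained per bin (intensity-weighted mean)
because annotation must work from accurate m/z, not bin labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureMatrix",
    "feature_name",
    "read_matrix",
    "bin_mz",
    "read_metadata",
    "validate_metadata",
]

#: Feature-table columns that are feature annotation, not sample intensities.
_META_COLS = ("name", "mz", "rt", "mz_weighted")


def feature_name(mz: float, rt: float) -> str:
    """Canonical feature name ``M<round(mz)>T<round(rt)>``.

    Rounding is round-half-to-even (numpy's rint), e.g. (705.5889, 366) ->
    "M706T366" and (100.5, 10.4) -> "M100T10".
    """
    if mz <= 0 or rt < 0:
        raise ValueError("feature_name requires mz > 0 and rt >= 0")
    return f"M{int(np.rint(mz))}T{int(np.rint(rt))}"


def _dedupe(names: Iterable[str]) -> list[str]:
    """Make names unique by appending _2, _3, ... to repeats."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        k = seen.get(n, 0) + 1
        seen[n] = k
        out.append(n if k == 1 else f"{n}_{k}")
    return out


@dataclass
class FeatureMatrix:
    """Samples x features intensity table with per-feature m/z and RT.

    Parameters
    ----------
    intensities
        DataFrame indexed by sample id, one column per feature name.
    features
        DataFrame indexed by feature name with columns ``mz`` and ``rt``
        (optionally ``mz_weighted`` for binned matrices).
    """

    intensities: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dup))}")
        if self.features.index.has_duplicates:
            dup = self.features.index[self.features.index.duplicated()]
            raise ValueError(f"duplicate feature names: {sorted(set(dup))}")
        if list(self.intensities.columns) != list(self.features.index):
            raise ValueError("intensity columns and feature table disagree")
        vals = self.intensities.to_numpy()
        if not np.all(np.isfinite(vals)):
            raise ValueError("intensities must be finite")
        if (self.features["mz"] <= 0).any():
            raise ValueError("feature m/z must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("feature RT must be non-negative")

    # -- basic accessors ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.index)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def mz(self) -> np.ndarray:
        return self.features["mz"].to_numpy()

    @property
    def rt(self) -> np.ndarray:
        return self.features["rt"].to_numpy()

    def values(self) -> np.ndarray:
        return self.intensities.to_numpy(dtype=float)

    # -- transforms --------------------------------------------------------
    def log2(self, pseudocount: float = 1.0) -> "FeatureMatrix":
        """Return log2(x + pseudocount) view; negligible for LC-MS-scale x."""
        return FeatureMatrix(np.log2(self.intensities + pseudocount),
                             self.features.copy())

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        names = list(names)
        missing = set(names) - set(self.features.index)
        if missing:
            raise KeyError(f"unknown features: {sorted(missing)[:5]}")
        return FeatureMatrix(self.intensities[names], self.features.loc[names])

    def drop_features(self, names: Iterable[str]) -> "FeatureMatrix":
        drop = set(names)
        keep = [n for n in self.feature_names if n not in drop]
        return self.subset_features(keep)

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.intensities.loc[list(sample_ids)],
                             self.features.copy())

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write features-as-rows TSV/CSV (columns: name, mz, rt, samples)."""
        sep = "," if str(path).endswith(".csv") else "\t"
        table = self.features.reset_index()
        first = table.columns[0]
        table = table.rename(columns={first: "name"})
        body = self.intensities.T.reset_index(drop=True)
        pd.concat([table, body], axis=1).to_csv(path, sep=sep, index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "FeatureMatrix":
        return read_matrix(path)

    @classmethod
    def from_arrays(
        cls,
        intensities: np.ndarray,
        sample_ids: Sequence[str],
        mz: Sequence[float],
        rt: Sequence[float],
        names: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        if names is None:
            names = _dedupe(feature_name(m, t) for m, t in zip(mz, rt))
        feats = pd.DataFrame({"mz": list(mz), "rt": list(rt)},
                             index=pd.Index(names, name="name"))
        inten = pd.DataFrame(np.asarray(intensities, dtype=float),
                             index=list(sample_ids), columns=list(names))
        return cls(inten, feats)


def read_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix from TSV/CSV.

    The file must contain ``mz`` and ``rt`` columns and at least one sample
    column; a ``name`` column is optional (names are generated from m/z and
    RT when absent). Malformed numeric cells are reported with row and
    column context; duplicate sample columns are an error; missing
    intensity cells are treated as 0 with a logged count.
    """
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    dup = sorted({c for c in header if header.count(c) > 1})
    if dup:
        raise ValueError(f"duplicate sample columns in {path.name}: {dup}")
    for required in ("mz", "rt"):
        if required not in header:
            raise ValueError(f"{path.name} lacks required column {required!r}")

    raw = pd.read_csv(path, sep=sep, dtype=str)
    sample_cols = [c for c in raw.columns if c not in _META_COLS]
    if not sample_cols:
        raise ValueError(f"{path.name} has no sample columns")

    numeric = {}
    for col in ["mz", "rt", *sample_cols]:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"malformed numeric cell in {path.name}: column {col!r}, "
                f"data row {row + 1}, value {raw[col].iloc[row]!r}"
            )
        numeric[col] = converted
    n_missing = int(sum(numeric[c].isna().sum() for c in sample_cols))
    if n_missing:
        logger.info("read_matrix: %d missing intensity cells set to 0 in %s",
                    n_missing, path.name)

    mz = numeric["mz"].to_numpy()
    rt = numeric["rt"].to_numpy()
    if "name" in raw.columns:
        names = list(raw["name"].astype(str))
    else:
        names = _dedupe(feature_name(m, t) for m, t in zip(mz, rt))
    inten = np.vstack([numeric[c].fillna(0.0).to_numpy() for c in sample_cols])
    fm = FeatureMatrix.from_arrays(inten, sample_cols, mz, rt, names)
    if "mz_weighted" in raw.columns:
        fm.features["mz_weighted"] = pd.to_numeric(raw["mz_weighted"]).to_numpy()
    return fm


def bin_mz(matrix: FeatureMatrix, width: float = 0.01) -> FeatureMatrix:
    """Pool features into fixed-width m/z bins, summing intensities.

    Bins are centred on integer multiples of ``width`` (feature j falls in
    bin ``round(mz_j / width)``), so e.g. 720.551 and 720.559 stay in
    separate 0.01 bins while 720.5525 and 720.5529 merge. Per-sample total
    intensity is conserved exactly, and binning an already-binned matrix is
    a no-op. Each bin keeps the intensity-weighted mean of its members'
    accurate m/z in ``mz_weighted`` so annotation can use un-binned masses.
    """
    if width <= 0:
        raise ValueError("bin width must be positive")
    mz = matrix.mz
    # tiny relative nudge so bin-centre m/z values round back to the same bin
    idx = np.rint(mz / width * (1 + 1e-12)).astype(np.int64)
    order = np.argsort(idx, kind="stable")

    vals = matrix.values()
    totals = vals.sum(axis=0)  # per-feature weight for representative m/z
    rows: list[dict] = []
    cols: list[np.ndarray] = []
    for b in np.unique(idx[order]):
        members = np.flatnonzero(idx == b)
        w = totals[members]
        w = w / w.sum() if w.sum() > 0 else np.full(len(members), 1 / len(members))
        rows.append({
            "mz": b * width,
            "rt": float(np.sum(w * matrix.rt[members])),
            "mz_weighted": float(np.sum(w * mz[members])),
        })
        cols.append(vals[:, members].sum(axis=1))
    names = _dedupe(feature_name(r["mz_weighted"], r["rt"]) for r in rows)
    feats = pd.DataFrame(rows, index=pd.Index(names, name="name"))
    inten = pd.DataFrame(np.column_stack(cols), index=matrix.sample_ids,
                         columns=names)
    return FeatureMatrix(inten, feats)


def bin_map(matrix: FeatureMatrix, binned: FeatureMatrix,
            width: float = 0.01) -> dict[str, str]:
    """Map original feature names to their bin's feature name.

    Useful for carrying feature-level bookkeeping (e.g. planted ground
    truth) across :func:`bin_mz`, whose merged bins get regenerated names.
    """
    idx = np.rint(matrix.mz / width * (1 + 1e-12)).astype(np.int64)
    bin_idx = np.rint(binned.mz / width * (1 + 1e-12)).astype(np.int64)
    by_bin = {int(b): name for b, name in zip(bin_idx, binned.feature_names)}
    return {name: by_bin[int(b)]
            for name, b in zip(matrix.feature_names, idx) if int(b) in by_bin}


# -- sample metadata -------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata table (sample_id, breed, diet, ...)."""
    path = Path(path)
    sep = "," if path.suffix == ".csv" else "\t"
    meta = pd.read_csv(path, sep=sep)
    for required in ("sample_id", "breed"):
        if required not in meta.columns:
            raise ValueError(f"metadata lacks required column {required!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
        raise ValueError(f"duplicate sample ids in metadata: {list(dup)}")
    return meta


def validate_metadata(matrix: FeatureMatrix, meta: pd.DataFrame) -> pd.DataFrame:
    """Check every matrix sample has exactly one metadata row; align order."""
    meta = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    missing = set(matrix.sample_ids) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    return meta.loc[matrix.sample_ids]
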