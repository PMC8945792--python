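"""Quantified signal-matrix ingest and the majority-presence filter.

The pipeline consumes relative quantitation tables from targeted LC-MS/MS
(MRM) acquisition: one row per lipid mediator, one column per sample,
non-negative arbitrary-unit signals already normalized to internal
standards upstream. Sample metadata carries the experimental design
(tissue, treatment, instillation protocol, replicate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import LipidRegistry, Miss, normalize_name

TISSUES = ("lung", "cortex")
TREATMENTS = ("CTRL", "DEP")
PROTOCOLS = ("acute", "subacute")
META_COLUMNS = ("tissue", "treatment", "protocol", "replicate")


class MatrixError(ValueError):
    """Malformed signal matrix or metadata."""


def _read_table(path: str | Path, **kw) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, **kw)


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata table, indexed by sample_id."""
    meta = _read_table(path)
    if "sample_id" not in meta.columns:
        raise MatrixError(f"{path}: metadata needs a sample_id column")
    meta = meta.set_index("sample_id")
    if meta.index.duplicated().any():
        dup = meta.index[meta.index.duplicated()].tolist()
        raise MatrixError(f"duplicate sample_id in metadata: {dup}")
    missing = set(META_COLUMNS) - set(meta.columns)
    if missing:
        raise MatrixError(f"metadata missing columns {sorted(missing)}")
    for col, levels in (
        ("tissue", TISSUES),
        ("treatment", TREATMENTS),
        ("protocol", PROTOCOLS),
    ):
        bad = set(meta[col].astype(str)) - set(levels)
        if bad:
            raise MatrixError(f"invalid {col} values {sorted(bad)}; expected {levels}")
    if (meta["replicate"].astype(int) < 1).any():
        raise MatrixError("replicate must be >= 1")
    return meta


@dataclass
class SignalMatrix:
    """Lipids x samples grid of non-negative signals with design metadata.

    ``values`` holds NaN for missing (blank) cells; zeros are true
    non-detects. ``unresolved`` lists lipid names that were kept under
    their normalized spelling because the registry could not place them.
    """

    values: pd.DataFrame  # lipids x samples, float, NaN = missing
    meta: pd.DataFrame  # indexed by sample_id
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise MatrixError(f"duplicate lipid ids: {dup}")
        if (self.values.to_numpy() < 0).any():
            i, j = np.argwhere(self.values.to_numpy() < 0)[0]
            raise MatrixError(
                f"negative signal for lipid {self.values.index[i]!r} in "
                f"sample {self.values.columns[j]!r}"
            )
        absent = set(self.values.columns) - set(self.meta.index)
        if absent:
            raise MatrixError(f"samples missing from metadata: {sorted(absent)}")
        # keep metadata aligned to the value columns
        self.meta = self.meta.loc[list(self.values.columns)]

    @property
    def lipids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_lipids(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def detected(self) -> pd.DataFrame:
        """Boolean grid: strictly positive and not missing."""
        return self.values.notna() & (self.values > 0)

    def subset_samples(self, sample_ids: list[str]) -> "SignalMatrix":
        return replace(
            self,
            values=self.values[sample_ids],
            meta=self.meta.loc[sample_ids],
        )

    def select(self, **criteria) -> "SignalMatrix":
        """Subset samples by metadata equality, e.g. ``select(tissue="lung")``."""
        mask = pd.Series(True, index=self.meta.index)
        for col, val in criteria.items():
            mask &= self.meta[col].astype(str) == str(val)
        return self.subset_samples(list(self.meta.index[mask]))


def read_matrix(
    values_path: str | Path,
    meta_path: str | Path,
    registry: LipidRegistry | None = None,
) -> SignalMatrix:
    """Read a quantitation table plus metadata into a :class:`SignalMatrix`.

    Lipid names are resolved through the registry when one is supplied;
    misses are kept under their normalized name and flagged, never
    dropped. Blank cells become missing; negative values are rejected
    naming the offending cell.
    """
    raw = _read_table(values_path, dtype=str)
    lipid_col = raw.columns[0]
    raw = raw.set_index(lipid_col)
    values = raw.apply(pd.to_numeric, errors="raise")
    meta = read_sample_meta(meta_path)

    ids, unresolved = [], []
    for name in values.index:
        if registry is None:
            ids.append(normalize_name(str(name)))
            continue
        hit = registry.resolve(str(name))
        if isinstance(hit, Miss):
            ids.append(hit.normalized)
            unresolved.append(str(name))
        else:
            ids.append(hit.canonical_id)
    values.index = pd.Index(ids, name="lipid")
    return SignalMatrix(values=values.astype(float), meta=meta, unresolved=unresolved)


def majority_presence_filter(
    m: SignalMatrix, min_presence: float = 0.5
) -> tuple[SignalMatrix, pd.DataFrame]:
    """Keep lipids detected in a strict majority of all samples.

    A lipid is detected in a sample when its signal is strictly positive
    and not missing; it is retained when detected in strictly more than
    ``min_presence`` of the samples (global, not per group). Returns the
    filtered matrix and a per-lipid report with detection counts.
    """
    if m.n_samples == 0 or m.n_lipids == 0:
        raise MatrixError("cannot filter an empty matrix")
    if not 0 <= min_presence < 1:
        raise ValueError("min_presence must be in [0, 1)")
    n_det = m.detected().sum(axis=1)
    keep = n_det > min_presence * m.n_samples
    report = pd.DataFrame(
        {
            "n_detected": n_det.astype(int),
            "n_samples": m.n_samples,
            "retained": keep,
        }
    )
    report.index.name = "lipid"
    filtered = replace(m, values=m.values.loc[keep])
    return filtered, report
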