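"""Long-format EMA data container and CSV I/O.

An :class:`EMADataset` wraps a pandas DataFrame with one row per
subject-occasion.  The canonical simulated schema has columns
``subject, day, beep, beep1, beep6, x2, x1, y, m`` (1-based subject/day/
beep indices), optional ``true_*`` columns retaining pre-masking values,
and NaN for missing cells.  Real datasets may carry arbitrary outcome and
covariate columns; only ``subject`` is mandatory.

Missing cells are written as empty fields and read from either empty
fields or the string "NA" (R interoperability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["EMADataset", "ModelArrays", "read_dataset", "preprocess"]

CANONICAL_COLUMNS = [
    "subject",
    "day",
    "beep",
    "beep1",
    "beep6",
    "x2",
    "x1",
    "y",
    "m",
]


class EMADataset:
    """Subject x occasion longitudinal table.

    Parameters
    ----------
    frame : pandas.DataFrame
        Long-format table, one row per scheduled occasion.  Must contain a
        ``subject`` column.  Missing values are NaN.
    validate : bool
        Run schema checks (subject-constant columns etc.) on construction.
    """

    def __init__(self, frame: pd.DataFrame, validate: bool = True):
        if "subject" not in frame.columns:
            raise ValueError("EMADataset requires a 'subject' column")
        self.frame = frame.reset_index(drop=True)
        if validate:
            self._validate()

    def _validate(self) -> None:
        f = self.frame
        if f["subject"].isna().any():
            bad = f.index[f["subject"].isna()].tolist()
            raise ValueError(f"missing subject id at rows {bad[:10]}")
        if "x2" in f.columns:
            nun = f.groupby("subject")["x2"].nunique(dropna=True)
            bad = nun[nun > 1]
            if len(bad):
                raise ValueError(
                    "x2 must be constant within subject; violated for "
                    f"subjects {bad.index.tolist()[:10]}"
                )
        if "m" in f.columns:
            m = f["m"].dropna()
            if not m.isin([0, 1]).all():
                raise ValueError("missingness indicator m must be 0/1")

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.frame["subject"].to_numpy())

    @property
    def n_subjects(self) -> int:
        return self.subjects.size

    def subject_codes(self) -> np.ndarray:
        """0-based contiguous subject codes aligned with rows."""
        return pd.Categorical(self.frame["subject"]).codes.astype(np.int64)

    def copy(self) -> "EMADataset":
        return EMADataset(self.frame.copy(), validate=False)

    def missing_mask(self, column: str) -> np.ndarray:
        return self.frame[column].isna().to_numpy()

    def ensure_missing_indicator(self, outcome: str = "y", name: str = "m"):
        """Derive m from the outcome's missingness when absent."""
        if name not in self.frame.columns:
            self.frame[name] = self.frame[outcome].isna().astype(float)
        return self

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, validate: bool = True) -> "EMADataset":
        frame = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
        return cls(frame, validate=validate)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, na_rep="")


def read_dataset(path, outcome: str = "y", validate: bool = True) -> EMADataset:
    """Read a long-format CSV; derive ``m`` from the outcome if absent."""
    data = EMADataset.from_csv(path, validate=validate)
    if outcome in data.frame.columns:
        data.ensure_missing_indicator(outcome)
    return data


def preprocess(data: EMADataset, transforms) -> EMADataset:
    """Apply declared column transforms, returning a new dataset.

    Supported transforms (applied in order):

    * ``("sqrt", col)`` — square-root transform; errors on negatives.
    * ``("scale", col, factor)`` — multiply by a constant (e.g., age/10).
    * ``("interaction", col_a, col_b, ...)`` — product column named
      ``"a:b[:c]"``.
    """
    frame = data.frame.copy()
    for spec in transforms:
        kind = spec[0]
        if kind == "sqrt":
            col = spec[1]
            neg = frame.index[frame[col] < 0].tolist()
            if neg:
                raise ValueError(f"sqrt of negative values in {col!r} at rows {neg[:10]}")
            frame[col] = np.sqrt(frame[col])
        elif kind == "scale":
            _, col, factor = spec
            frame[col] = frame[col] * factor
        elif kind == "interaction":
            cols = spec[1:]
            name = ":".join(cols)
            prod = frame[cols[0]].copy()
            for c in cols[1:]:
                prod = prod * frame[c]
            frame[name] = prod
        else:
            raise ValueError(f"unknown transform {kind!r}")
    return EMADataset(frame, validate=False)


@dataclass
class ModelArrays:
    """Design arrays extracted from an :class:`EMADataset` for one model.

    ``observed`` marks rows where the response (and every covariate used)
    is non-missing; only those rows enter the outcome likelihood.  The
    missingness indicator ``m`` is defined on *all* scheduled rows.
    """

    y: np.ndarray          # (n,) response, NaN where missing
    X_loc: np.ndarray      # (n, p) mean-model covariates
    X_scale: np.ndarray    # (n, ps) WS-variance covariates
    T: np.ndarray          # (n, q) missingness covariates (may be empty)
    m: np.ndarray          # (n,) missingness indicator
    subject: np.ndarray    # (n,) 0-based subject codes
    observed: np.ndarray   # (n,) bool
    n_subjects: int
    loc_names: tuple
    scale_names: tuple
    miss_names: tuple

    @classmethod
    def build(
        cls,
        data: EMADataset,
        response: str,
        loc_covariates,
        scale_covariates=None,
        missing: str | None = None,
        missing_covariates=(),
    ) -> "ModelArrays":
        f = data.frame
        loc_covariates = list(loc_covariates)
        scale_covariates = (
            list(scale_covariates) if scale_covariates is not None else loc_covariates
        )
        missing_covariates = list(missing_covariates)
        for col in {response, *loc_covariates, *scale_covariates, *missing_covariates}:
            if col not in f.columns:
                raise ValueError(f"column {col!r} not in dataset")
        y = f[response].to_numpy(dtype=float)
        X_loc = f[loc_covariates].to_numpy(dtype=float) if loc_covariates else np.empty((len(f), 0))
        X_scale = (
            f[scale_covariates].to_numpy(dtype=float) if scale_covariates else np.empty((len(f), 0))
        )
        T = (
            f[missing_covariates].to_numpy(dtype=float)
            if missing_covariates
            else np.empty((len(f), 0))
        )
        if missing is not None:
            m = f[missing].to_numpy(dtype=float)
            if np.isnan(m).any():
                raise ValueError("missingness indicator must be defined on all rows")
            if not np.isin(m, [0.0, 1.0]).all():
                raise ValueError("missingness indicator m must be 0/1")
        else:
            m = np.isnan(y).astype(float)
        cov_ok = np.ones(len(f), dtype=bool)
        if X_loc.size:
            cov_ok &= ~np.isnan(X_loc).any(axis=1)
        if X_scale.size:
            cov_ok &= ~np.isnan(X_scale).any(axis=1)
        observed = ~np.isnan(y) & cov_ok
        subject = data.subject_codes()
        return cls(
            y=y,
            X_loc=X_loc,
            X_scale=X_scale,
            T=T,
            m=m,
            subject=subject,
            observed=observed,
            n_subjects=int(subject.max()) + 1 if len(f) else 0,
            loc_names=tuple(loc_covariates),
            scale_names=tuple(scale_covariates),
            miss_names=tuple(missing_covariates),
        )
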