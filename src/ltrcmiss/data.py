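"""Data model and plain-text I/O for left-truncated right-censored samples.

A subject contributes an entry time ``L`` (time from the natural time
origin — e.g. diagnosis — to study entry), an observed time
``T = min(U, C)`` with event indicator ``delta = I(U <= C)``, a binary
covariate of interest ``X`` that may be missing, and a vector of fully
observed categorical covariates ``W``.  Subjects are only sampled if their
event happens after entry (``T > L``), which is the left-truncation
selection this package is about.  ``R = I(X observed)`` records
missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LTRCSample",
    "load_sample",
    "write_sample",
    "summarize",
    "ValidationError",
    "FormatError",
]

#: sentinels accepted (case-insensitively) for a missing X on load
_NA_SENTINELS = {"", "na", "nan"}


class FormatError(ValueError):
    """Raised when an input file lacks required structure (columns, header)."""


class ValidationError(ValueError):
    """Raised when field values violate the LTRC data contract."""


@dataclass
class LTRCSample:
    """One left-truncated right-censored sample.

    Attributes
    ----------
    entry : ndarray, shape (n,)
        Entry times ``L`` (>= 0; 0 means no truncation for that subject).
    time : ndarray, shape (n,)
        Observed times ``T``; every retained subject satisfies ``T > L``.
    status : ndarray, shape (n,)
        Event indicators ``delta`` in {0, 1}.
    x : ndarray, shape (n,)
        The binary covariate; ``nan`` where missing.
    w : ndarray, shape (n, k)
        Integer-coded categorical covariates, fully observed.
    r : ndarray, shape (n,)
        ``1`` where ``x`` is observed, ``0`` where missing.
    weight : ndarray, shape (n,)
        Positive per-subject weights (all 1 unless set by a weighting
        estimator).
    """

    entry: np.ndarray
    time: np.ndarray
    status: np.ndarray
    x: np.ndarray
    w: np.ndarray
    r: np.ndarray = field(default=None)  # type: ignore[assignment]
    weight: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.entry = np.asarray(self.entry, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.w = np.atleast_2d(np.asarray(self.w, dtype=int))
        if self.w.shape[0] != self.entry.shape[0] and self.w.shape[1] == self.entry.shape[0]:
            self.w = self.w.T
        if self.r is None:
            self.r = (~np.isnan(self.x)).astype(int)
        else:
            self.r = np.asarray(self.r, dtype=int)
        if self.weight is None:
            self.weight = np.ones_like(self.time)
        else:
            self.weight = np.asarray(self.weight, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = self.n
        for name in ("entry", "time", "status", "x", "r", "weight"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"field {name!r} has shape "
                                      f"{getattr(self, name).shape}, expected ({n},)")
        if self.w.shape[0] != n:
            raise ValidationError(f"w has {self.w.shape[0]} rows, expected {n}")
        if n < 2:
            raise ValidationError("sample must contain at least 2 subjects")
        if np.any(self.entry < 0):
            rows = np.flatnonzero(self.entry < 0)
            raise ValidationError(f"negative entry time at row(s) {rows.tolist()}")
        bad = self.time <= self.entry
        if np.any(bad):
            rows = np.flatnonzero(bad)
            raise ValidationError(
                f"time <= entry at row(s) {rows.tolist()}: retained subjects "
                "must satisfy T > L")
        if not np.isin(self.status, (0, 1)).all():
            raise ValidationError("status must be binary (0/1)")
        observed = ~np.isnan(self.x)
        if not np.isin(self.x[observed], (0.0, 1.0)).all():
            raise ValidationError("x must be 0/1 where observed")
        if not np.array_equal(self.r, observed.astype(int)):
            raise ValidationError("r must equal 1 exactly where x is observed")
        if np.any(self.weight <= 0) or not np.all(np.isfinite(self.weight)):
            raise ValidationError("weights must be positive and finite")
        if not self.status.any():
            raise ValidationError("sample must contain at least one event")

    @property
    def n(self) -> int:
        return self.entry.shape[0]

    @property
    def n_w(self) -> int:
        """Number of W columns."""
        return self.w.shape[1]

    def subset(self, mask: np.ndarray) -> "LTRCSample":
        """Row subset (boolean mask or index array); weights are carried over."""
        return LTRCSample(
            entry=self.entry[mask], time=self.time[mask],
            status=self.status[mask], x=self.x[mask], w=self.w[mask],
            r=self.r[mask], weight=self.weight[mask])

    def with_x(self, x: np.ndarray) -> "LTRCSample":
        """Copy of the sample with a fully observed covariate vector ``x``."""
        x = np.asarray(x, dtype=float)
        return replace(self, x=x, r=(~np.isnan(x)).astype(int))

    def with_weight(self, weight: np.ndarray) -> "LTRCSample":
        return replace(self, weight=np.asarray(weight, dtype=float))

    def design_matrix(self) -> np.ndarray:
        """Regression design ``(X, W-indicators)`` for the hazard model.

        W columns are treated as unordered categories: each is expanded to
        indicator columns for every level above its smallest code.  Binary
        0/1 columns therefore pass through unchanged.  Missing ``x`` entries
        propagate as ``nan`` (callers requiring complete data must impute or
        filter first).
        """
        return np.column_stack([self.x, expand_w(self.w)])

    def to_frame(self) -> pd.DataFrame:
        cols = {"entry": self.entry, "time": self.time, "status": self.status,
                "x": self.x}
        for k in range(self.n_w):
            cols[f"w{k + 1}"] = self.w[:, k]
        return pd.DataFrame(cols)


def expand_w(w: np.ndarray) -> np.ndarray:
    """Indicator expansion of integer-coded W, reference = smallest code."""
    w = np.atleast_2d(np.asarray(w, dtype=int))
    blocks = []
    for k in range(w.shape[1]):
        levels = np.unique(w[:, k])
        for lev in levels[1:]:
            blocks.append((w[:, k] == lev).astype(float))
    if not blocks:
        return np.empty((w.shape[0], 0))
    return np.column_stack(blocks)


_ROLES = ("entry", "time", "status", "x")


def load_sample(path, column_map: dict | None = None) -> LTRCSample:
    """Read a delimited-text sample (RFC-4180 CSV with a header row).

    Parameters
    ----------
    path : str or path-like
    column_map : dict, optional
        Maps file column names to roles ``entry``/``time``/``status``/``x``;
        columns whose role starts with ``w`` become W columns in the given
        order.  Defaults to the canonical names ``entry,time,status,x,w1,...``.

    Missing ``x`` may be encoded as an empty field or the literal ``NA``
    (case-insensitive); no numeric sentinel is recognised.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if column_map:
        inverse = {src: role for src, role in column_map.items()}
        df = df.rename(columns=inverse)
    missing = [c for c in _ROLES if c not in df.columns]
    if missing:
        raise FormatError(f"required column(s) missing: {missing}")
    w_cols = sorted((c for c in df.columns if c.startswith("w") and c[1:].isdigit()),
                    key=lambda c: int(c[1:]))

    def _num(col, kind=float):
        try:
            return df[col].astype(kind).to_numpy()
        except ValueError as exc:
            raise ValidationError(f"column {col!r}: {exc}") from exc

    xraw = df["x"].str.strip()
    is_na = xraw.str.lower().isin(_NA_SENTINELS)
    x = np.full(len(df), np.nan)
    if (~is_na).any():
        try:
            x[~is_na] = xraw[~is_na].astype(float)
        except ValueError as exc:
            raise ValidationError(f"column 'x': {exc}") from exc
    w = (np.column_stack([_num(c, float) for c in w_cols]).astype(int)
         if w_cols else np.empty((len(df), 0), dtype=int))
    return LTRCSample(entry=_num("entry"), time=_num("time"),
                      status=_num("status").astype(int), x=x, w=w)


def write_sample(sample: LTRCSample, path) -> None:
    """Write the canonical CSV (missing x as empty field)."""
    df = sample.to_frame()
    df["status"] = df["status"].astype(int)
    df.to_csv(path, index=False, na_rep="")


def summarize(sample: LTRCSample) -> dict:
    """Basic descriptives: size, events, censoring/missingness fractions.

    Returns n, the event count, the censoring fraction ``1 - mean(delta)``,
    the missingness fraction ``theta_hat = 1 - mean(r)``, and the frequency
    of ``x = 1`` among subjects with ``x`` observed.
    """
    n = sample.n
    events = int(sample.status.sum())
    obs = sample.r == 1
    return {
        "n": n,
        "events": events,
        "censoring_fraction": 1.0 - events / n,
        "missingness_fraction": 1.0 - sample.r.mean(),
        "x_frequency_observed": float(sample.x[obs].mean()) if obs.any() else np.nan,
    }
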