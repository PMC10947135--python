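"""Longitudinal panel containers.

A :class:`Panel` holds one simulated or user-supplied cohort in wide
(person-major) layout: one row per person, one column per visit for each
time-varying quantity.  The external exchange format is a long-format
table (one row per person-visit) with explicit observation indicators,
round-tripped losslessly through CSV.

Conventions
-----------
* ``T`` visits indexed ``t = 0..T-1``; baseline is ``t = 0``.
* ``r_x[i, t] == 0``  iff  ``x[i, t]`` is missing (NaN); same for ``r_y``/``y``.
* ``c[i, t] == 1`` marks monotone drop-out (absorbing: once 1, always 1).
* Treatment ``a`` and baseline covariates are never missing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

LONG_COLUMNS = ["id", "t", "b_bin", "b_cont", "x", "a", "y", "r_x", "r_y", "c"]


@dataclass
class Panel:
    """Wide-format longitudinal cohort."""

    b_bin: np.ndarray   # (n,) {0,1}
    b_cont: np.ndarray  # (n,) continuous baseline covariate (age-like)
    x: np.ndarray       # (n, T) time-varying confounder, NaN where unobserved
    a: np.ndarray       # (n, T) {0,1} treatment, fully observed
    y: np.ndarray       # (n, T) outcome, NaN where unobserved
    r_x: np.ndarray     # (n, T) {0,1} observation indicator for x
    r_y: np.ndarray     # (n, T) {0,1} observation indicator for y
    c: np.ndarray       # (n, T) {0,1} monotone drop-out indicator

    def __post_init__(self) -> None:
        n, T = self.x.shape
        for name in ("a", "y", "r_x", "r_y", "c"):
            arr = getattr(self, name)
            if arr.shape != (n, T):
                raise ValueError(f"panel field {name!r} has shape {arr.shape}, expected {(n, T)}")
        for name in ("b_bin", "b_cont"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"panel field {name!r} must have shape ({n},)")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def T(self) -> int:
        return self.x.shape[1]

    def copy(self) -> "Panel":
        return replace(
            self,
            b_bin=self.b_bin.copy(), b_cont=self.b_cont.copy(),
            x=self.x.copy(), a=self.a.copy(), y=self.y.copy(),
            r_x=self.r_x.copy(), r_y=self.r_y.copy(), c=self.c.copy(),
        )

    # ------------------------------------------------------------------
    # observation bookkeeping
    # ------------------------------------------------------------------
    def observed(self) -> np.ndarray:
        """(n, T) boolean: both x and y observed at the visit."""
        return (self.r_x == 1) & (self.r_y == 1)

    def is_complete(self) -> bool:
        return bool(np.all(self.r_x == 1) and np.all(self.r_y == 1))

    def is_monotone(self) -> bool:
        """True when missingness is absorbing for every person.

        Once a person has an unobserved visit (x or y), every later visit
        must be fully unobserved (both x and y).
        """
        any_missing = (self.r_x == 0) | (self.r_y == 0)
        fully_missing = (self.r_x == 0) & (self.r_y == 0)
        started = np.cumsum(any_missing, axis=1) > 0
        # strictly after the first missing visit everything must be blanked
        after = np.zeros_like(started)
        after[:, 1:] = started[:, :-1]
        return bool(np.all(fully_missing[after]))

    def validate(self) -> None:
        """Check the indicator/value coherence invariants; raise on violation."""
        if not np.array_equal(self.r_x == 0, np.isnan(self.x)):
            raise ValueError("r_x indicators inconsistent with NaNs in x")
        if not np.array_equal(self.r_y == 0, np.isnan(self.y)):
            raise ValueError("r_y indicators inconsistent with NaNs in y")
        if np.any((self.a != 0) & (self.a != 1)):
            raise ValueError("treatment must be binary and fully observed")
        c_abs = np.maximum.accumulate(self.c, axis=1)
        if not np.array_equal(c_abs, self.c):
            raise ValueError("drop-out indicator must be absorbing")
        dropped = self.c == 1
        if np.any(self.r_x[dropped] == 1) or np.any(self.r_y[dropped] == 1):
            raise ValueError("observed cells found after drop-out")

    # ------------------------------------------------------------------
    # long-format exchange
    # ------------------------------------------------------------------
    def to_long(self) -> pd.DataFrame:
        n, T = self.n, self.T
        ids = np.repeat(np.arange(n), T)
        ts = np.tile(np.arange(T), n)
        return pd.DataFrame({
            "id": ids,
            "t": ts,
            "b_bin": np.repeat(self.b_bin.astype(int), T),
            "b_cont": np.repeat(self.b_cont, T),
            "x": self.x.ravel(),
            "a": self.a.astype(int).ravel(),
            "y": self.y.ravel(),
            "r_x": self.r_x.astype(int).ravel(),
            "r_y": self.r_y.astype(int).ravel(),
            "c": self.c.astype(int).ravel(),
        })

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "Panel":
        missing_cols = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValueError(f"long-format panel lacks columns: {missing_cols}")
        df = df.sort_values(["id", "t"], kind="stable")
        counts = df.groupby("id", sort=True)["t"].agg(["size", "min", "max"])
        T = int(counts["size"].iloc[0])
        if not ((counts["size"] == T).all() and (counts["min"] == 0).all()
                and (counts["max"] == T - 1).all()):
            raise ValueError("every id must contribute visits 0..T-1 exactly once")
        n = len(counts)

        def grid(col, dtype=float):
            return df[col].to_numpy(dtype=dtype).reshape(n, T)

        panel = cls(
            b_bin=grid("b_bin", int)[:, 0],
            b_cont=grid("b_cont")[:, 0],
            x=grid("x"),
            a=grid("a", int),
            y=grid("y"),
            r_x=grid("r_x", int),
            r_y=grid("r_y", int),
            c=grid("c", int),
        )
        panel.validate()
        return panel


def write_panel_csv(panel: Panel, path) -> None:
    """Write long-format CSV with missing cells left empty."""
    panel.to_long().to_csv(path, index=False, na_rep="", float_format="%.17g")


def read_panel_csv(path) -> Panel:
    # round_trip parser: the default fast parser drops the last ULP
    return Panel.from_long(pd.read_csv(path, float_precision="round_trip"))
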