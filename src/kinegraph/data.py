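"""Containers for multivariate, mixed-type time-series datasets.

A dataset is a long-format :class:`pandas.DataFrame` with one row per time
step, optionally grouped into independent trajectories by a trajectory-id
column.  Variables are continuous, categorical, or *contextual*: a contextual
variable encodes an externally set experimental condition (e.g. treatment,
co-culture presence) and is constant within each trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

KIND_CONTINUOUS = "continuous"
KIND_CATEGORICAL = "categorical"
KIND_CONTEXTUAL = "contextual"

#: columns with at most this many distinct integer-like values are treated as
#: categorical when kinds are inferred from a raw table
_MAX_INFERRED_LEVELS = 10


@dataclass(frozen=True)
class VariableSpec:
    """Name and statistical type of one variable.

    Parameters
    ----------
    name : str
        Column name in the dataset.
    kind : {"continuous", "categorical", "contextual"}
        Contextual variables are time-invariant experimental conditions;
        they are handled like categorical variables by the estimators but
        are pinned to the contemporaneous layer of time-unfolded graphs and
        never receive incoming causal arrows.
    n_levels : int or None
        Number of categories (categorical/contextual only).
    """

    name: str
    kind: str = KIND_CONTINUOUS
    n_levels: int | None = None

    def __post_init__(self):
        if self.kind not in (KIND_CONTINUOUS, KIND_CATEGORICAL, KIND_CONTEXTUAL):
            raise ValueError(f"unknown variable kind: {self.kind!r}")

    @property
    def is_discrete(self) -> bool:
        return self.kind in (KIND_CATEGORICAL, KIND_CONTEXTUAL)


def infer_spec(name: str, values: pd.Series, contextual: bool = False) -> VariableSpec:
    """Infer a :class:`VariableSpec` from a column of raw values."""
    vals = pd.Series(values)
    if contextual:
        return VariableSpec(name, KIND_CONTEXTUAL, int(vals.nunique()))
    if vals.dtype == object or isinstance(vals.dtype, pd.CategoricalDtype) or vals.dtype == bool:
        return VariableSpec(name, KIND_CATEGORICAL, int(vals.nunique()))
    arr = vals.to_numpy()
    finite = arr[np.isfinite(arr.astype(float))]
    uniq = np.unique(finite)
    if uniq.size <= _MAX_INFERRED_LEVELS and np.allclose(uniq, np.round(uniq)):
        return VariableSpec(name, KIND_CATEGORICAL, int(uniq.size))
    return VariableSpec(name, KIND_CONTINUOUS)


class TimeSeriesDataset:
    """Mixed-type multivariate trajectories with contextual condition columns.

    Parameters
    ----------
    frame : DataFrame
        Long-format table; rows within a trajectory are consecutive time
        steps in acquisition order.
    trajectory_col : str, optional
        Column holding the trajectory id.  ``None`` means a single
        trajectory.
    contextual : sequence of str
        Names of contextual (time-invariant condition) columns.
    specs : sequence of VariableSpec, optional
        Explicit variable specs; inferred from dtypes when omitted.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        trajectory_col: str | None = None,
        contextual: Sequence[str] = (),
        specs: Sequence[VariableSpec] | None = None,
    ):
        self.frame = frame.reset_index(drop=True)
        self.trajectory_col = trajectory_col
        contextual = tuple(contextual)
        var_cols = [c for c in frame.columns if c != trajectory_col]
        if specs is None:
            specs = [infer_spec(c, frame[c], contextual=c in contextual) for c in var_cols]
        self.specs: list[VariableSpec] = list(specs)
        self._spec_by_name = {s.name: s for s in self.specs}
        for c in contextual:
            if c not in self._spec_by_name:
                raise KeyError(f"contextual column {c!r} not in dataset")
        self._check_contextual_constant()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(
        cls,
        path,
        trajectory_col: str | None = None,
        contextual: Sequence[str] = (),
        sep: str | None = None,
    ) -> "TimeSeriesDataset":
        frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        if trajectory_col is not None and trajectory_col not in frame.columns:
            raise ValueError(f"missing trajectory column {trajectory_col!r} in {path}")
        for c in contextual:
            if c not in frame.columns:
                raise ValueError(f"missing contextual column {c!r} in {path}")
        return cls(frame, trajectory_col=trajectory_col, contextual=contextual)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    # -- access ------------------------------------------------------------
    @property
    def variable_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec(self, name: str) -> VariableSpec:
        try:
            return self._spec_by_name[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def trajectories(self) -> Iterable[pd.DataFrame]:
        """Yield per-trajectory frames (variable columns only), in stable order."""
        cols = self.variable_names
        if self.trajectory_col is None:
            yield self.frame[cols]
            return
        for _, grp in self.frame.groupby(self.trajectory_col, sort=True):
            yield grp[cols]

    @property
    def n_trajectories(self) -> int:
        if self.trajectory_col is None:
            return 1
        return int(self.frame[self.trajectory_col].nunique())

    def __len__(self) -> int:
        return len(self.frame)

    # -- validation ---------------------------------------------------------
    def _check_contextual_constant(self) -> None:
        ctx = [s.name for s in self.specs if s.kind == KIND_CONTEXTUAL]
        if not ctx:
            return
        for traj in self.trajectories():
            for c in ctx:
                if traj[c].nunique() > 1:
                    raise ValueError(
                        f"contextual variable {c!r} varies within a trajectory"
                    )
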