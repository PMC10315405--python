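"""Categorical consumption data container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class DataError(ValueError):
    """Raised when observed data violate the model's input contract."""


@dataclass
class ConsumptionMatrix:
    """A person-by-food matrix of categorical consumption levels.

    Parameters
    ----------
    y:
        ``(n, p)`` integer array with levels in ``{1..d}`` (level 1 is
        "no consumption").
    subgroup:
        ``(n,)`` integer array of subgroup indices in ``{1..S}``.
    d:
        Number of consumption levels (4 in the dietary application:
        none / low / medium / high).
    item_names, subgroup_names:
        Optional labels; defaults are generated.
    person_ids:
        Optional per-person identifiers.
    """

    y: np.ndarray
    subgroup: np.ndarray
    d: int = 4
    item_names: list[str] = field(default_factory=list)
    subgroup_names: list[str] = field(default_factory=list)
    person_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int64)
        self.subgroup = np.asarray(self.subgroup, dtype=np.int64)
        if self.y.ndim != 2:
            raise DataError(f"y must be 2-D, got shape {self.y.shape}")
        n, p = self.y.shape
        if self.subgroup.shape != (n,):
            raise DataError(
                f"subgroup has shape {self.subgroup.shape}, expected ({n},)"
            )
        if n == 0 or p == 0:
            raise DataError("empty consumption matrix")
        if self.y.min() < 1 or self.y.max() > self.d:
            bad = np.argwhere((self.y < 1) | (self.y > self.d))[0]
            raise DataError(
                f"consumption level out of range 1..{self.d} at "
                f"row {bad[0]}, column {bad[1]}"
            )
        if self.subgroup.min() < 1:
            raise DataError("subgroup indices must start at 1")
        S = int(self.subgroup.max())
        counts = np.bincount(self.subgroup - 1, minlength=S)
        if (counts == 0).any():
            empty = int(np.argmin(counts)) + 1
            raise DataError(f"subgroup {empty} is empty")
        if not self.item_names:
            self.item_names = [f"item_{j + 1}" for j in range(p)]
        if len(self.item_names) != p:
            raise DataError("item_names length does not match p")
        if not self.subgroup_names:
            self.subgroup_names = [f"subgroup_{s + 1}" for s in range(S)]
        if len(self.subgroup_names) != S:
            raise DataError("subgroup_names length does not match S")
        if not self.person_ids:
            self.person_ids = list(range(1, n + 1))
        if len(self.person_ids) != n:
            raise DataError("person_ids length does not match n")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.y.shape[1]

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_names)

    def subgroup_sizes(self) -> np.ndarray:
        return np.bincount(self.subgroup - 1, minlength=self.n_subgroups)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=self.item_names)
        df.insert(0, "subgroup", self.subgroup)
        df.insert(0, "id", self.person_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        d: int = 4,
        subgroup_col: str = "subgroup",
        id_col: str = "id",
        subgroup_names: list[str] | None = None,
    ) -> "ConsumptionMatrix":
        item_cols = [c for c in df.columns if c not in (subgroup_col, id_col)]
        sub = df[subgroup_col].to_numpy()
        if sub.dtype.kind not in "iu":
            # Map labels to 1..S in order of first appearance.
            codes, uniques = pd.factorize(df[subgroup_col])
            sub = codes + 1
            subgroup_names = subgroup_names or [str(u) for u in uniques]
        ids = df[id_col].tolist() if id_col in df.columns else []
        return cls(
            y=df[item_cols].to_numpy(),
            subgroup=np.asarray(sub),
            d=d,
            item_names=item_cols,
            subgroup_names=subgroup_names or [],
            person_ids=ids,
        )

    @classmethod
    def from_csv(cls, path, d: int = 4, subgroup_col: str = "subgroup",
                 id_col: str = "id") -> "ConsumptionMatrix":
        return cls.from_frame(pd.read_csv(path), d=d,
                              subgroup_col=subgroup_col, id_col=id_col)
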