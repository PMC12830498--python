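"""Score-table containers, validation, and reshaping.

The universal data container is a long-format table with one row per
(participant, item) observation.  Items are opaque labels; scores are
numeric on the instrument scale.  Missing scores are allowed and are
excluded item-wise from every downstream count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScaleSpec",
    "ScoreTable",
    "read_score_table",
    "wide_to_long",
    "long_to_wide",
]


@dataclass(frozen=True)
class ScaleSpec:
    """Bounds of the measurement scale.

    Parameters
    ----------
    minimum, maximum : float
        Lower and upper bound of the instrument scale (e.g. 1 and 7 for a
        seven-point rating scale).  ``maximum`` must exceed ``minimum``.
    discrete : bool
        Whether scores are whole numbers on the scale.
    """

    minimum: float
    maximum: float
    discrete: bool = False

    def __post_init__(self) -> None:
        if not self.maximum > self.minimum:
            raise ValueError(
                f"maximum ({self.maximum}) must exceed minimum ({self.minimum})"
            )

    @property
    def half_range(self) -> float:
        return (self.maximum - self.minimum) / 2.0

    @classmethod
    def infer(cls, scores: np.ndarray | pd.Series) -> "ScaleSpec":
        """Infer bounds from observed data (for unbounded instruments)."""
        s = np.asarray(scores, dtype=float)
        s = s[~np.isnan(s)]
        if s.size == 0:
            raise ValueError("cannot infer scale bounds from no data")
        discrete = bool(np.allclose(s, np.round(s)))
        return cls(minimum=float(s.min()), maximum=float(s.max()), discrete=discrete)


class ScoreTable:
    """Long-format item-level observations.

    Wraps a :class:`pandas.DataFrame` with columns ``participant``, ``item``
    and ``score``.  Construction validates the invariants: every row carries
    an item label, and every retained item has at least two non-missing
    scores (a standard error is undefined otherwise); items failing that are
    dropped with a warning.

    Parameters
    ----------
    data : pandas.DataFrame
        Must contain the three columns (after renaming via ``columns``).
    columns : mapping, optional
        Maps the canonical names ``participant``/``item``/``score`` to the
        column names actually present in ``data``.
    scale : ScaleSpec, optional
        Declared scale bounds; when given, all non-missing scores must lie
        within them.
    """

    REQUIRED = ("participant", "item", "score")

    def __init__(
        self,
        data: pd.DataFrame,
        columns: Mapping[str, str] | None = None,
        scale: ScaleSpec | None = None,
    ) -> None:
        df = data.copy()
        if columns:
            rename = {v: k for k, v in columns.items()}
            df = df.rename(columns=rename)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise KeyError(f"score table is missing column(s): {missing}")
        df = df.loc[:, list(self.REQUIRED)]
        if df["item"].isna().any():
            raise ValueError("every row must carry a non-missing item identifier")
        df["item"] = df["item"].astype(str)
        df["score"] = pd.to_numeric(df["score"], errors="coerce")

        counts = df.dropna(subset=["score"]).groupby("item", sort=False)["score"].size()
        thin = set(df["item"].unique()) - set(counts[counts >= 2].index)
        if thin:
            warnings.warn(
                f"dropped {len(thin)} item(s) with fewer than 2 non-missing "
                f"scores: {sorted(thin)[:5]}{'...' if len(thin) > 5 else ''}",
                stacklevel=2,
            )
            df = df[~df["item"].isin(thin)]
        if df["item"].nunique() == 0:
            raise ValueError("no items with at least 2 non-missing scores remain")

        if scale is not None:
            s = df["score"].dropna()
            if ((s < scale.minimum) | (s > scale.maximum)).any():
                raise ValueError(
                    "scores fall outside the declared scale bounds "
                    f"[{scale.minimum}, {scale.maximum}]"
                )
        self.data = df.reset_index(drop=True)
        self.scale = scale

    # -- constructors -------------------------------------------------

    @classmethod
    def from_wide(
        cls,
        wide: pd.DataFrame,
        participant: str | None = None,
        scale: ScaleSpec | None = None,
    ) -> "ScoreTable":
        return cls(wide_to_long(wide, participant=participant), scale=scale)

    # -- accessors ----------------------------------------------------

    @property
    def items(self) -> list[str]:
        return list(self.data["item"].unique())

    @property
    def n_items(self) -> int:
        return self.data["item"].nunique()

    def n_per_item(self) -> pd.Series:
        """Count of non-missing scores per item."""
        return (
            self.data.dropna(subset=["score"])
            .groupby("item", sort=False)["score"]
            .size()
        )

    def scores_by_item(self) -> dict[str, np.ndarray]:
        """Non-missing scores per item, as float arrays."""
        out: dict[str, np.ndarray] = {}
        for item, grp in self.data.groupby("item", sort=False):
            out[item] = grp["score"].dropna().to_numpy(dtype=float)
        return out

    def to_wide(self) -> pd.DataFrame:
        return long_to_wide(self.data)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.data)

    def __repr__(self) -> str:  # pragma: no cover
        return f"ScoreTable({self.n_items} items, {len(self.data)} rows)"


def read_score_table(
    path: str | Path,
    participant: str = "participant",
    item: str = "item",
    score: str = "score",
    sep: str | None = None,
    scale: ScaleSpec | None = None,
) -> ScoreTable:
    """Read a delimited long-format file into a validated :class:`ScoreTable`.

    ``sep=None`` sniffs comma vs. tab from the file extension
    (``.tsv``/``.tab`` → tab, else comma).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    for col in (participant, item, score):
        if col not in df.columns:
            raise KeyError(
                f"column {col!r} not found in {path.name}; "
                f"available: {list(df.columns)}"
            )
    return ScoreTable(
        df,
        columns={"participant": participant, "item": item, "score": score},
        scale=scale,
    )


def wide_to_long(wide: pd.DataFrame, participant: str | None = None) -> pd.DataFrame:
    """Melt a participants × items matrix into the long three-column layout.

    Every column after the participant column is taken to be an item; missing
    cells become missing scores (and stay in the table so per-item counts are
    explicit).
    """
    df = wide.copy()
    if participant is None:
        participant = df.columns[0]
    item_cols = [c for c in df.columns if c != participant]
    if len(set(item_cols)) != len(item_cols):
        raise ValueError("duplicate item column names in wide table")
    if not item_cols:
        raise ValueError("wide table has no item columns")
    long = df.melt(
        id_vars=[participant], value_vars=item_cols,
        var_name="item", value_name="score",
    ).rename(columns={participant: "participant"})
    return long


def long_to_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long layout back to a participants × items matrix."""
    wide = long.pivot(index="participant", columns="item", values="score")
    wide = wide.reset_index()
    wide.columns.name = None
    return wide
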