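"""Typed symmetric distance/identity matrices.

One container serves the three pairwise statistics the pipeline moves
between stages: ANI percentages (diagonal 100), SNP counts (diagonal 0) and
normalized phylogenetic distances (diagonal 0, values in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from straindyad.errors import InputError

KINDS = ("ani_percent", "snp_count", "npd")


@dataclass
class DistanceMatrix:
    """Symmetric taxon-by-taxon matrix with a declared statistic kind.

    Parameters
    ----------
    taxa : ordered taxon identifiers (unique).
    values : square array, symmetric; diagonal must be 100 for
        ``ani_percent`` and 0 otherwise. NaN encodes "undefined" (e.g. an
        ANI with no retained fragments) and is permitted off-diagonal.
    kind : one of ``ani_percent``, ``snp_count``, ``npd``.
    """

    taxa: list[str]
    values: np.ndarray
    kind: str
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InputError(f"unknown matrix kind {self.kind!r}; expected one of {KINDS}")
        self.taxa = [str(t) for t in self.taxa]
        if len(set(self.taxa)) != len(self.taxa):
            raise InputError("taxa must be unique")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise InputError(f"values shape {self.values.shape} does not match {n} taxa")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0),
            np.where(finite & finite.T, self.values.T, 0.0),
            atol=1e-12,
        ):
            raise InputError("matrix must be symmetric")
        if np.any(self.values[finite] < 0):
            raise InputError("distances must be >= 0")
        diag = 100.0 if self.kind == "ani_percent" else 0.0
        if n and not np.allclose(np.diag(self.values), diag):
            raise InputError(f"diagonal must be {diag} for kind {self.kind!r}")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def __len__(self) -> int:
        return len(self.taxa)

    def get(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise InputError(f"unknown taxon {exc.args[0]!r}") from None

    def submatrix(self, taxa: Sequence[str]) -> "DistanceMatrix":
        idx = [self._index[t] for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)], self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = self.kind
        df.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path, kind: str | None = None) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        k = kind if kind is not None else str(df.index.name)
        return cls(list(df.columns), df.to_numpy(dtype=float), k)
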