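"""Text front end: term-document counts -> tf-idf features and
posting-date-based similarity matrices.

Tokenization/stemming/stop-word removal are standard preprocessing and out of
scope here; the module consumes an already-counted term-document matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mixture import SimilarityMatrix


@dataclass
class TermDocumentMatrix:
    """Nonnegative integer counts, documents x terms, with optional dates."""

    counts: np.ndarray
    terms: list[str]
    doc_dates: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if (self.counts < 0).any() or not np.issubdtype(
            self.counts.dtype, np.integer
        ):
            raise ValueError("counts must be nonnegative integers")
        if len(self.terms) != self.counts.shape[1]:
            raise ValueError("one term per column required")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("terms must be unique")

    @classmethod
    def from_csv(cls, path, date_col: str | None = "date",
                 sep: str = ",") -> "TermDocumentMatrix":
        df = pd.read_csv(path, sep=sep)
        dates = None
        if date_col is not None and date_col in df.columns:
            dates = df[date_col]
            df = df.drop(columns=[date_col])
        return cls(df.to_numpy(dtype=int), list(df.columns), dates)


def tfidf_transform(tdm: TermDocumentMatrix,
                    n_t: int | None = None) -> tuple[np.ndarray, list[str]]:
    """tf-idf features: entry (i, j) = tf_i(w_j) * log(n_t / df(w_j)).

    Natural log; terms appearing in every document map to all-zero columns;
    terms appearing in no document are dropped with a warning.  Returns the
    feature matrix and the retained term list.
    """
    counts = tdm.counts
    n = n_t if n_t is not None else counts.shape[0]
    if n != counts.shape[0]:
        raise ValueError("n_t must equal the number of documents")
    df_counts = (counts > 0).sum(axis=0)
    keep = df_counts > 0
    if not keep.all():
        dropped = [t for t, k in zip(tdm.terms, keep) if not k]
        warnings.warn(f"dropping terms with zero document frequency: {dropped}")
    counts = counts[:, keep]
    df_counts = df_counts[keep]
    idf = np.log(n / df_counts)
    return counts * idf, [t for t, k in zip(tdm.terms, keep) if k]


def similarity_from_dates(doc_dates) -> SimilarityMatrix:
    """Pairwise similarity s_ii' = 1 / (1 + days between posting dates)."""
    parsed = []
    for row, value in enumerate(pd.Series(doc_dates)):
        try:
            parsed.append(pd.to_datetime(value))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"unparseable date at row {row}: {value!r}") from exc
    days = np.array([d.toordinal() for d in parsed], dtype=float)
    delta = np.abs(days[:, None] - days[None, :])
    S = 1.0 / (1.0 + delta)
    np.fill_diagonal(S, 0.0)
    return SimilarityMatrix(S)
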