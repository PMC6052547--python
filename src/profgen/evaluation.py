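"""Scoring predictions and ranked homology hit lists.

Two families of metrics:

* Profile accuracy — per-position cosine similarity between predicted and
  target probability columns, and its mean-by-position aggregation across a
  dataset (ragged ends are ignored, not padded).

* Homology-search benchmarking — ranked hits are labeled TP / FP / unknown
  from a SCOP-style structural annotation (same superfamily: TP; different
  fold or class: FP; same fold but different superfamily, or a self-hit:
  unknown), each counted hit contributes weight 1/|query superfamily| to its
  ROC axis to negate superfamily-size bias, and the headline statistic is
  the partial AUC up to a weighted false-positive budget of one FP per query
  on average (equal to the number of distinct superfamilies), normalized to
  [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence as TypingSequence, Tuple

import numpy as np
import pandas as pd

from .types import ProfileMatrix

__all__ = [
    "positional_cosine",
    "mean_cosine_by_position",
    "ScopAnnotation",
    "LabeledHit",
    "label_hits",
    "RocCurve",
    "weighted_roc",
    "pauc",
    "relative_sensitivity",
    "read_hits",
    "read_annotation",
]


def positional_cosine(pred: ProfileMatrix, target: ProfileMatrix) -> np.ndarray:
    """Cosine similarity between prediction and target, per position."""
    a = pred.matrix if isinstance(pred, ProfileMatrix) else np.asarray(pred, dtype=float)
    b = target.matrix if isinstance(target, ProfileMatrix) else np.asarray(target, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    if np.any(na == 0) or np.any(nb == 0):
        raise ValueError("cosine undefined for a zero-norm profile row")
    return (a * b).sum(axis=1) / (na * nb)


def mean_cosine_by_position(
    pairs: TypingSequence[Tuple[ProfileMatrix, ProfileMatrix]]
) -> np.ndarray:
    """Mean cosine at each position across a dataset of (pred, target) pairs.

    Sequences shorter than the longest simply stop contributing past their
    length; position p of the result averages over exactly the pairs that
    reach p.
    """
    if not pairs:
        raise ValueError("no pairs given")
    n_max = max(p.n for p, _ in pairs)
    total = np.zeros(n_max)
    count = np.zeros(n_max, dtype=int)
    for pred, target in pairs:
        c = positional_cosine(pred, target)
        total[: c.size] += c
        count[: c.size] += 1
    return total / count


# ---------------------------------------------------------------------------
# weighted ROC / pAUC
# ---------------------------------------------------------------------------


@dataclass
class ScopAnnotation:
    """Domain -> (class, fold, superfamily, family) structural lineage."""

    lineage: Dict[str, Tuple[str, str, str, str]]

    def __post_init__(self):
        self._sf_sizes: Dict[str, int] = {}
        for _, (_, _, sf, _) in self.lineage.items():
            self._sf_sizes[sf] = self._sf_sizes.get(sf, 0) + 1

    def superfamily(self, domain: str) -> str:
        return self._require(domain)[2]

    def superfamily_size(self, sf: str) -> int:
        return self._sf_sizes[sf]

    @property
    def n_superfamilies(self) -> int:
        return len(self._sf_sizes)

    def _require(self, domain: str) -> Tuple[str, str, str, str]:
        try:
            return self.lineage[domain]
        except KeyError:
            raise KeyError(f"domain {domain!r} is not annotated") from None


@dataclass(frozen=True)
class LabeledHit:
    query: str
    subject: str
    evalue: float
    label: str  # "TP" | "FP" | "unknown"
    query_superfamily: str


def label_hits(
    hits: TypingSequence[Tuple[str, str, float]], annotation: ScopAnnotation
) -> List[LabeledHit]:
    """Label ranked (query, subject, e-value) hits, preserving order.

    Same superfamily -> TP; different class or fold -> FP; same fold but
    different superfamily -> unknown; self-hits -> unknown.
    """
    out = []
    for query, subject, evalue in hits:
        q_cl, q_fo, q_sf, _ = annotation._require(query)
        s_cl, s_fo, s_sf, _ = annotation._require(subject)
        if query == subject:
            label = "unknown"
        elif q_sf == s_sf:
            label = "TP"
        elif q_cl != s_cl or q_fo != s_fo:
            label = "FP"
        else:
            label = "unknown"
        out.append(LabeledHit(query, subject, evalue, label, q_sf))
    return out


@dataclass
class RocCurve:
    """Cumulative weighted (FP, TP) points, starting at (0, 0)."""

    fp: np.ndarray
    tp: np.ndarray

    def __post_init__(self):
        self.fp = np.asarray(self.fp, dtype=float)
        self.tp = np.asarray(self.tp, dtype=float)
        if self.fp.shape != self.tp.shape or self.fp.ndim != 1:
            raise ValueError("fp and tp must be 1-D arrays of equal length")
        if np.any(np.diff(self.fp) < 0) or np.any(np.diff(self.tp) < 0):
            raise ValueError("ROC coordinates must be non-decreasing")


def weighted_roc(labeled: TypingSequence[LabeledHit], annotation: ScopAnnotation) -> RocCurve:
    """Superfamily-weighted ROC over hits already sorted by significance
    (ascending e-value, ties in stable input order).

    Each counted TP/FP hit adds 1/|query superfamily| to its axis; unknown
    hits contribute to neither. A point is appended after every counted hit.
    """
    ordered = sorted(labeled, key=lambda h: h.evalue)
    fp = [0.0]
    tp = [0.0]
    for hit in ordered:
        if hit.label == "unknown":
            continue
        size = annotation.superfamily_size(hit.query_superfamily)
        if size <= 0:
            raise ValueError(f"superfamily {hit.query_superfamily!r} has no members")
        w = 1.0 / size
        if hit.label == "TP":
            fp.append(fp[-1])
            tp.append(tp[-1] + w)
        else:
            fp.append(fp[-1] + w)
            tp.append(tp[-1])
    return RocCurve(np.array(fp), np.array(tp))


def pauc(curve: RocCurve, fp_limit: float, tp_max: float) -> float:
    """Normalized partial AUC for weighted FP in [0, fp_limit].

    Trapezoidal area with interpolation at the cutoff; if the curve ends
    before the budget it is extended horizontally at its final TP level.
    Both axes are normalized (FP by fp_limit, TP by tp_max) so the statistic
    lies in [0, 1].
    """
    if curve.fp.size == 0:
        raise ValueError("empty ROC curve")
    if fp_limit <= 0:
        raise ValueError("fp_limit must be positive")
    if tp_max < curve.tp.max():
        raise ValueError("tp_max must be at least the maximum TP on the curve")
    fp = np.append(curve.fp, max(fp_limit, curve.fp[-1]))
    tp = np.append(curve.tp, curve.tp[-1])
    area = 0.0
    for k in range(1, fp.size):
        x0, x1 = fp[k - 1], fp[k]
        y0, y1 = tp[k - 1], tp[k]
        if x0 >= fp_limit:
            break
        if x1 > fp_limit:
            # interpolate the TP level at the cutoff
            y1 = y0 + (y1 - y0) * (fp_limit - x0) / (x1 - x0)
            x1 = fp_limit
        area += 0.5 * (y0 + y1) * (x1 - x0)
    return area / (fp_limit * tp_max)


def relative_sensitivity(pauc_a: float, pauc_b: float) -> float:
    """Ratio of two pAUC values (method A relative to method B)."""
    if pauc_b == 0:
        raise ValueError("reference pAUC is zero")
    return pauc_a / pauc_b


# ---------------------------------------------------------------------------
# tab-separated inputs
# ---------------------------------------------------------------------------


def read_hits(path) -> List[Tuple[str, str, float]]:
    """Read a tab-separated hit list: query, subject, e-value."""
    df = pd.read_csv(path, sep="\t", header=None, names=["query", "subject", "evalue"])
    return list(df.itertuples(index=False, name=None))


def read_annotation(path) -> ScopAnnotation:
    """Read a tab-separated annotation: domain, class, fold, superfamily, family."""
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["domain", "class", "fold", "superfamily", "family"], dtype=str,
    )
    lineage = {
        d: (c, f, sf, fam)
        for d, c, f, sf, fam in zip(
            df["domain"], df["class"], df["fold"], df["superfamily"], df["family"]
        )
    }
    return ScopAnnotation(lineage)
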