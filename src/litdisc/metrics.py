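"""Edge-weight metrics computed from per-pair sentence/document counts.

All statistical metrics operate on sentence-level counts via the 2x2 table

    O11 = n_ab            O12 = n_a - n_ab
    O21 = n_b - n_ab      O22 = N - n_a - n_b + n_ab

with N = total sentences; only ``doc_count`` uses document-level counts.
Natural logarithms throughout.  Degenerate margins (e.g. an entity present in
every sentence) yield finite conventional values rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable


@dataclass(frozen=True)
class ContingencyCounts:
    """Sufficient statistics for one entity pair.

    ``n_*`` are sentence counts, ``d_*`` document counts, ``n_sent``/``n_doc``
    the corpus totals.  Invariants: 0 < n_ab <= min(n_a, n_b) and
    n_a + n_b - n_ab <= n_sent (document analogues likewise).
    """

    n_ab: int
    n_a: int
    n_b: int
    n_sent: int
    d_ab: int = 0
    d_a: int = 0
    d_b: int = 0
    n_doc: int = 0

    def validate(self) -> None:
        if not (0 < self.n_ab <= min(self.n_a, self.n_b)):
            raise ValueError(f"need 0 < n_ab <= min(n_a, n_b): {self}")
        if self.n_a + self.n_b - self.n_ab > self.n_sent:
            raise ValueError(f"union exceeds sentence total: {self}")
        if self.d_ab and not (0 < self.d_ab <= min(self.d_a, self.d_b)):
            raise ValueError(f"need 0 < d_ab <= min(d_a, d_b): {self}")
        if self.d_a + self.d_b - self.d_ab > self.n_doc:
            raise ValueError(f"union exceeds document total: {self}")

    def swapped(self) -> "ContingencyCounts":
        return ContingencyCounts(n_ab=self.n_ab, n_a=self.n_b, n_b=self.n_a,
                                 n_sent=self.n_sent, d_ab=self.d_ab,
                                 d_a=self.d_b, d_b=self.d_a, n_doc=self.n_doc)


def count(c: ContingencyCounts) -> float:
    """Number of sentences in which the pair co-occurs."""
    return float(c.n_ab)


def doc_count(c: ContingencyCounts) -> float:
    """Number of documents in which the pair co-occurs."""
    return float(c.d_ab)


def jaccard(c: ContingencyCounts) -> float:
    """|sentences(a) ∩ sentences(b)| / |sentences(a) ∪ sentences(b)|."""
    return c.n_ab / (c.n_a + c.n_b - c.n_ab)


def scp(c: ContingencyCounts) -> float:
    """Symmetric conditional probability P(a|b) * P(b|a) = P(ab)^2 / (P(a)P(b))."""
    return c.n_ab * c.n_ab / (c.n_a * c.n_b)


def npmi(c: ContingencyCounts) -> float:
    """Pointwise mutual information normalized by -ln P(ab); 1 when P(ab)=1."""
    p_ab = c.n_ab / c.n_sent
    if p_ab == 1.0:
        return 1.0
    p_a = c.n_a / c.n_sent
    p_b = c.n_b / c.n_sent
    return math.log(p_ab / (p_a * p_b)) / (-math.log(p_ab))


def chi_squared(c: ContingencyCounts) -> float:
    """Pearson chi-squared statistic of the 2x2 table (no continuity correction)."""
    n = c.n_sent
    o11 = c.n_ab
    o12 = c.n_a - c.n_ab
    o21 = c.n_b - c.n_ab
    o22 = n - c.n_a - c.n_b + c.n_ab
    denom = c.n_a * c.n_b * (n - c.n_a) * (n - c.n_b)
    if denom == 0:
        # a margin is degenerate (entity in every or no sentence): no evidence
        # of (in)dependence is measurable
        return 0.0
    det = o11 * o22 - o12 * o21
    return n * det * det / denom


def t_test(c: ContingencyCounts) -> float:
    """Collocation t statistic: (P(ab) - P(a)P(b)) / sqrt(P(ab)(1-P(ab))/N)."""
    n = c.n_sent
    p_ab = c.n_ab / n
    p_a = c.n_a / n
    p_b = c.n_b / n
    var = p_ab * (1.0 - p_ab) / n
    if var == 0.0:
        return 0.0
    return (p_ab - p_a * p_b) / math.sqrt(var)


def llr(c: ContingencyCounts) -> float:
    """Log-likelihood ratio statistic 2 * sum O_ij ln(O_ij / E_ij), 0 ln 0 = 0."""
    n = c.n_sent
    obs = (c.n_ab, c.n_a - c.n_ab, c.n_b - c.n_ab, n - c.n_a - c.n_b + c.n_ab)
    row = (c.n_a, c.n_a, n - c.n_a, n - c.n_a)
    col = (c.n_b, n - c.n_b, c.n_b, n - c.n_b)
    total = 0.0
    for o, r, k in zip(obs, row, col):
        if o == 0:
            continue
        e = r * k / n
        total += o * math.log(o / e)
    # tiny negative residue from float rounding on exact-independence tables
    return max(2.0 * total, 0.0)


METRICS: dict[str, Callable[[ContingencyCounts], float]] = {
    "count": count,
    "doc_count": doc_count,
    "jaccard": jaccard,
    "scp": scp,
    "npmi": npmi,
    "chi_squared": chi_squared,
    "t_test": t_test,
    "llr": llr,
}

METRIC_NAMES = tuple(METRICS)


def compute_metric(name: str, c: ContingencyCounts) -> float:
    """Evaluate the named metric on one pair's contingency counts."""
    try:
        fn = METRICS[name]
    except KeyError:
        raise ValueError(f"unknown metric {name!r}; known: {', '.join(METRICS)}") from None
    return fn(c)
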