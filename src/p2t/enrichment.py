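"""Top-k enrichment of a gold target set.

Given a ranked target list and an externally curated set of gold targets
(e.g. the approved targets for an indication), the question is whether
the top k of the ranking contains more gold targets than chance. With N
scored targets of which K are gold, the number of gold targets among the
top k draws is hypergeometric, and the over-representation p-value is the
upper tail P(X >= k_hits).

The universe is the run's own scored-target list, not all genes: the test
asks whether the *ranking* concentrates gold targets at the top, given
which targets entered the run at all.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence, Union

from pydantic import BaseModel
from scipy.stats import hypergeom

from .scoring import ScoredTarget

__all__ = [
    "EnrichmentResult",
    "hypergeom_tail",
    "evaluate_topk",
    "read_gold_set",
]


class EnrichmentResult(BaseModel):
    """Outcome of a top-k over-representation test."""

    k_hits: int
    n_drawn: int
    K_gold: int
    N_universe: int
    p_value: float


def hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` universe size, ``K`` gold items in the universe, ``n`` draws,
    ``k`` observed gold items among the draws. Computed through the
    log-gamma-based survival function, so it is stable for large counts.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 < n <= N:
        raise ValueError(f"need 0 < n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"need 0 <= k <= min(n, K), got k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def evaluate_topk(
    scored: Sequence[ScoredTarget],
    gold: Iterable[str],
    k: int,
) -> EnrichmentResult:
    """Test gold-target enrichment among the top ``k`` ranked targets.

    Gold membership is matched by gene symbol, case-insensitively, and
    restricted to symbols actually present in the scored universe.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if not scored:
        raise ValueError("scored target list is empty")
    if k > len(scored):
        raise ValueError(f"k={k} exceeds universe size {len(scored)}")
    gold_upper = {g.strip().upper() for g in gold if g.strip()}
    universe = [st.record.symbol.upper() for st in scored]
    K_gold = sum(1 for sym in universe if sym in gold_upper)
    ordered = sorted(scored, key=lambda st: st.rank)
    k_hits = sum(1 for st in ordered[:k] if st.record.symbol.upper() in gold_upper)
    p = hypergeom_tail(k_hits, k, K_gold, len(scored)) if K_gold else 1.0
    return EnrichmentResult(
        k_hits=k_hits,
        n_drawn=k,
        K_gold=K_gold,
        N_universe=len(scored),
        p_value=p,
    )


def read_gold_set(path: Union[str, Path]) -> set[str]:
    """Read a gold set: one symbol per line, ``#`` starts a comment."""
    symbols: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        text = line.split("#", 1)[0].strip()
        if text:
            symbols.add(text)
    return symbols
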