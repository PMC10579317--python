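"""ELO-based pairwise quality ranking and rank agreement.

Raters compare image pairs ("select the higher quality"); each rater's
comparisons drive a standard logistic ELO scheme (initial rating 1500,
K = 32, base-10/400 expected score). A tournament runs a fixed number of
rounds, each a random perfect matching of the items. The consensus ranking
averages ratings across raters, and agreement with the IQCS ranking is
measured by Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import ValidationError

INITIAL_RATING = 1500.0
DEFAULT_K = 32.0


@dataclass
class EloState:
    ratings: dict = field(default_factory=dict)
    k_factor: float = DEFAULT_K
    history: list = field(default_factory=list)  # (round, item_a, item_b, winner)

    def to_frame(self) -> pd.DataFrame:
        rv = rank_items(self.ratings)
        return pd.DataFrame(
            {"item": list(self.ratings),
             "elo": [self.ratings[i] for i in self.ratings],
             "rank": [rv[i] for i in self.ratings]}
        )


def expected_score(r_a: float, r_b: float) -> float:
    return 1.0 / (1.0 + 10.0 ** ((r_b - r_a) / 400.0))


def elo_update(r_a: float, r_b: float, outcome: str,
               k_factor: float = DEFAULT_K) -> tuple[float, float]:
    """One zero-sum ELO update; ``outcome`` is 'a_wins' or 'b_wins'."""
    if outcome not in ("a_wins", "b_wins"):
        raise ValidationError(f"unknown outcome {outcome!r}")
    e_a = expected_score(r_a, r_b)
    s_a = 1.0 if outcome == "a_wins" else 0.0
    delta = k_factor * (s_a - e_a)
    return r_a + delta, r_b - delta


def run_tournament(items, comparator, rounds: int = 15, seed: int = 0,
                   k_factor: float = DEFAULT_K) -> EloState:
    """Random-matching ELO tournament.

    Each round draws a uniform random perfect matching (one item sits out
    when the count is odd) and applies one update per pair; ``comparator``
    returns the preferred item of each pair. Deterministic given the seed.
    """
    items = list(items)
    if len(items) < 2:
        raise ValidationError("a tournament needs at least 2 items")
    rng = np.random.default_rng(seed)
    state = EloState(ratings={it: INITIAL_RATING for it in items},
                     k_factor=k_factor)
    for rnd in range(rounds):
        order = rng.permutation(len(items))
        for i in range(0, len(items) - 1, 2):
            a, b = items[order[i]], items[order[i + 1]]
            winner = comparator(a, b)
            if winner not in (a, b):
                raise ValidationError("comparator must return one of the pair")
            outcome = "a_wins" if winner == a else "b_wins"
            state.ratings[a], state.ratings[b] = elo_update(
                state.ratings[a], state.ratings[b], outcome, k_factor
            )
            state.history.append((rnd, a, b, winner))
    return state


def rank_items(scores: dict) -> dict:
    """Rank by descending score; rank 1 is best; ties get average ranks."""
    items = list(scores)
    vals = np.array([scores[i] for i in items], dtype=float)
    ranks = sps.rankdata(-vals, method="average")
    return dict(zip(items, ranks))


def consensus_ranking(states: list[EloState]) -> dict:
    """Rank by the average ELO rating across raters' final states."""
    if not states:
        raise ValidationError("need at least one rating state")
    item_sets = [set(s.ratings) for s in states]
    if any(s != item_sets[0] for s in item_sets):
        raise ValidationError("all states must rate the identical item set")
    items = list(states[0].ratings)
    mean = {it: float(np.mean([s.ratings[it] for s in states])) for it in items}
    return rank_items(mean)


def spearman_rank_corr(rank_a: dict, rank_b: dict) -> float:
    """Spearman's rho between two rankings of the same items."""
    if set(rank_a) != set(rank_b):
        raise ValidationError("rankings must cover the same items")
    if len(rank_a) < 2:
        raise ValidationError("need at least 2 items")
    items = list(rank_a)
    rho = sps.spearmanr([rank_a[i] for i in items],
                        [rank_b[i] for i in items]).statistic
    return float(rho)


def simulated_rater(true_quality: dict, tau: float = 0.0, seed: int = 0):
    """Comparator preferring the higher-true-quality item; with ``tau > 0``
    the preference is logistic-noisy with temperature tau, with ``tau = 0``
    it is noiseless (deterministic, ties broken toward the first item)."""
    rng = np.random.default_rng(seed)

    def compare(a, b):
        delta = true_quality[a] - true_quality[b]
        if tau <= 0:
            return a if delta >= 0 else b
        p_a = 1.0 / (1.0 + np.exp(-delta / tau))
        return a if rng.random() < p_a else b

    return compare


def history_frame(state: EloState) -> pd.DataFrame:
    return pd.DataFrame(state.history,
                        columns=["round", "item_a", "item_b", "winner"])
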