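"""Iowa Gambling Task: deck payoff schedule, choice simulation, scoring.

Four decks, each paying a fixed reward per card with scheduled penalties
recurring over a 10-card cycle.  Decks 1 and 3 pay $150/card and net a gain
over 10 cards; decks 2 and 4 pay $200/card and net a loss.  Decks 1 and 2
carry infrequent (one large) penalties, decks 3 and 4 frequent (several
small) penalties.  Performance is the net-advantageous score: selections
from decks 1+3 minus selections from decks 2+4.

The schedule is data, not code: magnitudes and penalty positions live in a
:class:`DeckSchedule` instance and can be swapped wholesale.  The default
uses the classic +/-$250 expected net per 10 cards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADVANTAGEOUS = (1, 3)
DISADVANTAGEOUS = (2, 4)


@dataclass(frozen=True)
class Deck:
    """One deck: fixed reward per card, penalties at positions in a 10-card cycle."""

    reward: float
    penalties: dict[int, float]  # position in cycle (0-9) -> penalty dollars
    cycle: int = 10

    @property
    def penalty_frequency(self) -> int:
        """Penalty events per cycle."""
        return len(self.penalties)

    def expected_net_per_cycle(self) -> float:
        return self.reward * self.cycle - sum(self.penalties.values())

    def outcome(self, position: int) -> tuple[float, float]:
        """(win, loss) for the given draw position (0-based) within the deck."""
        return self.reward, self.penalties.get(position % self.cycle, 0.0)


@dataclass(frozen=True)
class DeckSchedule:
    """The four-deck payoff schedule, indexed 1-4."""

    decks: dict[int, Deck]

    def __post_init__(self) -> None:
        if set(self.decks) != {1, 2, 3, 4}:
            raise ValueError("schedule must define decks 1-4")

    def validate(self) -> None:
        """Check the structural constraints the task design requires."""
        d = self.decks
        if not (d[1].reward == d[3].reward < d[2].reward == d[4].reward):
            raise ValueError("decks 1/3 must pay less per card than decks 2/4")
        for good in ADVANTAGEOUS:
            if d[good].expected_net_per_cycle() <= 0:
                raise ValueError(f"deck {good} must net a long-term gain")
        for bad in DISADVANTAGEOUS:
            if d[bad].expected_net_per_cycle() >= 0:
                raise ValueError(f"deck {bad} must net a long-term loss")
        if not (
            max(d[1].penalty_frequency, d[2].penalty_frequency)
            < min(d[3].penalty_frequency, d[4].penalty_frequency)
        ):
            raise ValueError("decks 1/2 must penalize less frequently than 3/4")


def default_schedule() -> DeckSchedule:
    """Classic magnitudes: $150/$200 rewards, expected net +/-$250 per 10 cards."""
    schedule = DeckSchedule(
        decks={
            1: Deck(reward=150.0, penalties={4: 1250.0}),
            2: Deck(reward=200.0, penalties={8: 2250.0}),
            3: Deck(reward=150.0, penalties={2: 250.0, 4: 250.0, 6: 250.0,
                                             8: 250.0, 9: 250.0}),
            4: Deck(reward=200.0, penalties={1: 450.0, 3: 450.0, 5: 450.0,
                                             7: 450.0, 9: 450.0}),
        }
    )
    schedule.validate()
    return schedule


@dataclass
class IGTRecord:
    """Trial-level log of one task block."""

    trials: pd.DataFrame  # columns: trial, deck, win, loss, total
    block_index: int = 1
    n_trials: int = 60

    def __post_init__(self) -> None:
        required = {"trial", "deck", "win", "loss", "total"}
        missing = required - set(self.trials.columns)
        if missing:
            raise ValueError(f"trial log missing columns {sorted(missing)}")

    def deck_counts(self) -> dict[int, int]:
        counts = self.trials[self.trials["deck"] > 0]["deck"].value_counts()
        return {d: int(counts.get(d, 0)) for d in (1, 2, 3, 4)}

    def final_total(self) -> float:
        return float(self.trials["total"].iloc[-1]) if len(self.trials) else 0.0


POLICIES = ("uniform-random", "epsilon-greedy")


def simulate_agent(
    schedule: DeckSchedule,
    policy: str = "epsilon-greedy",
    n_trials: int = 60,
    seed: int = 0,
    epsilon: float = 0.1,
    miss_prob: float = 0.0,
    block_index: int = 1,
) -> IGTRecord:
    """Simulate one agent playing ``n_trials`` cards.

    Policies: "uniform-random" picks decks uniformly; "epsilon-greedy"
    tracks each deck's running mean net payoff and exploits the best-valued
    deck (ties broken toward the lowest deck id), exploring uniformly with
    probability ``epsilon``.  Trials missed with probability ``miss_prob``
    (no response within the 2 s window) are logged with deck 0 and count
    toward no deck.  Deterministic under ``seed``.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    draws = {d: 0 for d in (1, 2, 3, 4)}  # position within each deck
    value_sum = {d: 0.0 for d in (1, 2, 3, 4)}
    rows = []
    total = 0.0
    for trial in range(1, n_trials + 1):
        if miss_prob > 0 and rng.random() < miss_prob:
            rows.append({"trial": trial, "deck": 0, "win": 0.0, "loss": 0.0,
                         "total": total})
            continue
        if policy == "uniform-random" or (epsilon > 0 and rng.random() < epsilon):
            deck = int(rng.integers(1, 5))
        else:
            # greedy on running mean net payoff; untried decks count as 0
            means = {
                d: (value_sum[d] / draws[d]) if draws[d] else 0.0
                for d in (1, 2, 3, 4)
            }
            deck = min(means, key=lambda d: (-means[d], d))
        win, loss = schedule.decks[deck].outcome(draws[deck])
        draws[deck] += 1
        value_sum[deck] += win - loss
        total += win - loss
        rows.append({"trial": trial, "deck": deck, "win": win, "loss": loss,
                     "total": total})
    return IGTRecord(trials=pd.DataFrame(rows), block_index=block_index,
                     n_trials=n_trials)


def net_advantageous(record: IGTRecord) -> int:
    """Selections from decks 1+3 minus selections from decks 2+4."""
    if len(record.trials) == 0:
        raise ValueError("empty trial record")
    counts = record.deck_counts()
    return (counts[1] + counts[3]) - (counts[2] + counts[4])
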