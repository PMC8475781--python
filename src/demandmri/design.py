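"""Block/trial schedule generation for the matched-difficulty demand experiment.

The experiment crosses domain (semantic vs. perceptual matching) with
difficulty (easy vs. difficult) in a five-condition block design: each run
holds six 16-s blocks of each of the four active conditions plus six rest
blocks, for 30 blocks (480 s) per run.  Active blocks contain eight go/no-go
matching trials at a 2-s SOA; the proportion of "match" (go) trials varies
pseudorandomly between 2/8 and 6/8 per block.  The semantic-difficult
condition is adaptive: its items come in three difficulty sub-levels, and the
sub-level presented tracks the participant's running accuracy so that the two
difficult conditions stay matched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ACTIVE_CONDITIONS = (
    "semantic_easy",
    "semantic_difficult",
    "perceptual_easy",
    "perceptual_difficult",
)
REST = "rest"
CONDITIONS = ACTIVE_CONDITIONS + (REST,)

BLOCK_S = 16.0
SOA_S = 2.0
TRIALS_PER_BLOCK = 8
BLOCKS_PER_CONDITION = 6
N_BLOCKS = BLOCKS_PER_CONDITION * len(CONDITIONS)
RUN_S = N_BLOCKS * BLOCK_S  # 480 s
MATCH_COUNT_RANGE = (2, 6)  # inclusive; 25%..75% of 8 trials
ADAPTIVE_THRESHOLD = 0.05


@dataclass(frozen=True)
class Block:
    condition: str
    onset_s: float
    duration_s: float = BLOCK_S


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered condition blocks for one run; onsets contiguous from 0."""

    blocks: tuple[Block, ...]
    run_duration_s: float = RUN_S

    def validate(self) -> None:
        counts = {c: 0 for c in CONDITIONS}
        t = 0.0
        for b in self.blocks:
            counts[b.condition] += 1
            if abs(b.onset_s - t) > 1e-9 or abs(b.duration_s - BLOCK_S) > 1e-9:
                raise ValueError("blocks must be contiguous 16-s intervals")
            t += b.duration_s
        per = len(self.blocks) // len(CONDITIONS)
        if any(v != per for v in counts.values()):
            raise ValueError("conditions must occur equally often")
        if abs(t - self.run_duration_s) > 1e-9:
            raise ValueError("run duration mismatch")


@dataclass(frozen=True)
class Trial:
    onset_in_block_s: float
    is_match: bool
    sub_level: int | None = None  # 1..3, semantic-difficult only


@dataclass(frozen=True)
class TrialSchedule:
    """Per-block trial lists aligned with a BlockSchedule (rest blocks empty)."""

    trials: tuple[tuple[Trial, ...], ...]
    soa_s: float = SOA_S


@dataclass
class AdaptiveState:
    """Running accuracies feeding the semantic-difficult sub-level rule.

    Counts accumulate over scored trials of the two difficult conditions;
    accuracy is cumulative within session (the simplest reading of tracking
    "current relative accuracies").
    """

    sem_correct: int = 0
    sem_total: int = 0
    perc_correct: int = 0
    perc_total: int = 0
    threshold: float = ADAPTIVE_THRESHOLD

    @property
    def sem_accuracy(self) -> float | None:
        return self.sem_correct / self.sem_total if self.sem_total else None

    @property
    def perc_accuracy(self) -> float | None:
        return self.perc_correct / self.perc_total if self.perc_total else None

    def record(self, condition: str, correct: bool) -> None:
        if condition == "semantic_difficult":
            self.sem_total += 1
            self.sem_correct += int(correct)
        elif condition == "perceptual_difficult":
            self.perc_total += 1
            self.perc_correct += int(correct)


def select_sublevel(state: AdaptiveState) -> int:
    """Sub-level (1 easiest .. 3 hardest) for the next semantic-difficult block.

    Hardest if semantic accuracy exceeds perceptual by more than the 5%
    threshold, easiest if it trails by more than the threshold, middle
    otherwise.  Before any difficult-condition trial has been scored the rule
    cold-starts at the middle sub-level.
    """
    sem, perc = state.sem_accuracy, state.perc_accuracy
    if sem is None or perc is None:
        return 2
    diff = sem - perc
    if diff > state.threshold:
        return 3
    if diff < -state.threshold:
        return 1
    return 2


def generate_run_schedule(
    seed: int, *, max_consecutive: int | None = None,
    blocks_per_condition: int = BLOCKS_PER_CONDITION,
) -> BlockSchedule:
    """Uniform pseudorandom permutation of the 30-block condition multiset.

    ``max_consecutive`` optionally forbids more than that many same-condition
    blocks in a row (rejection sampling); by default no such constraint is
    imposed.  ``blocks_per_condition`` defaults to the experiment's six;
    smaller values give scaled-down runs for calibration simulations.
    """
    rng = np.random.default_rng(seed)
    labels = [c for c in CONDITIONS for _ in range(blocks_per_condition)]
    while True:
        order = rng.permutation(len(labels))
        seq = [labels[i] for i in order]
        if max_consecutive is None or _max_run_length(seq) <= max_consecutive:
            break
    blocks = tuple(
        Block(condition=c, onset_s=i * BLOCK_S) for i, c in enumerate(seq)
    )
    sched = BlockSchedule(blocks=blocks, run_duration_s=len(seq) * BLOCK_S)
    sched.validate()
    return sched


def _max_run_length(seq: list[str]) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def build_trial_schedule(schedule: BlockSchedule, seed: int) -> TrialSchedule:
    """Eight trials per active block at onsets 0,2,...,14 s within the block.

    Each active block's match count is drawn uniformly from {2..6} and match
    positions are a random subset of the eight slots.  Rest blocks carry no
    trials.  Sub-levels are left unset here; they are assigned adaptively at
    presentation time (see :class:`AdaptiveState`).
    """
    rng = np.random.default_rng(seed)
    per_block: list[tuple[Trial, ...]] = []
    for block in schedule.blocks:
        if block.condition == REST:
            per_block.append(())
            continue
        n_match = int(rng.integers(MATCH_COUNT_RANGE[0], MATCH_COUNT_RANGE[1] + 1))
        match_slots = set(rng.choice(TRIALS_PER_BLOCK, size=n_match, replace=False))
        per_block.append(
            tuple(
                Trial(onset_in_block_s=i * SOA_S, is_match=i in match_slots)
                for i in range(TRIALS_PER_BLOCK)
            )
        )
    return TrialSchedule(trials=tuple(per_block))


def count_condition_items(schedules: list[BlockSchedule]) -> dict[str, int]:
    """Item slots per active condition across the given runs (6 blocks x 8)."""
    counts = {c: 0 for c in ACTIVE_CONDITIONS}
    for sched in schedules:
        for block in sched.blocks:
            if block.condition != REST:
                counts[block.condition] += TRIALS_PER_BLOCK
    return counts


def events_frame(schedule: BlockSchedule, trials: TrialSchedule) -> pd.DataFrame:
    """BIDS-style events table: one row per trial, rest blocks as single rows."""
    rows = []
    for block, block_trials in zip(schedule.blocks, trials.trials):
        if block.condition == REST:
            rows.append(
                dict(onset=block.onset_s, duration=block.duration_s,
                     trial_type=REST, is_match="n/a", sub_level="n/a")
            )
            continue
        for tr in block_trials:
            rows.append(
                dict(
                    onset=block.onset_s + tr.onset_in_block_s,
                    duration=trials.soa_s,
                    trial_type=block.condition,
                    is_match=int(tr.is_match),
                    sub_level=tr.sub_level if tr.sub_level is not None else "n/a",
                )
            )
    return pd.DataFrame(rows)


def write_events_tsv(path, schedule: BlockSchedule, trials: TrialSchedule) -> None:
    events_frame(schedule, trials).to_csv(path, sep="\t", index=False)


def events_to_blocks(events: pd.DataFrame) -> list[Block]:
    """Reconstruct 16-s condition blocks from a per-trial events table."""
    blocks = []
    for onset0 in np.arange(0, events["onset"].max() + 1e-9, BLOCK_S):
        rows = events[(events["onset"] >= onset0 - 1e-9)
                      & (events["onset"] < onset0 + BLOCK_S - 1e-9)]
        if rows.empty:
            continue
        cond = rows["trial_type"].iloc[0]
        blocks.append(Block(condition=cond, onset_s=float(onset0)))
    return blocks
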