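"""In silico evolution: Metropolis-Hastings sampling over sequence space.

A trajectory starts at the wild type and proposes single amino-acid
exchanges; improving moves are always accepted and deteriorating moves are
accepted with probability exp(delta / T), so the chain can traverse fitness
valleys that a greedy walk could not.  A *trust radius* bounds the Hamming
distance from the wild type: at the boundary, proposals are restricted to
already-mutated positions (substitution or reversion) so the chain stays
irreducible inside the ball instead of wasting proposals on rejected
excursions.

Stage-1 defaults follow the published protocol (2000 trajectories of 500
steps, trust radius 2, temperatures 0.3 / 0.03 / 0.003); stage 2 used 750
trajectories of 500 steps at trust radius 3 and T = 0.03.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .potts import Mutation, PottsModel, VariantGenotype

__all__ = [
    "EvolutionConfig",
    "TrajectoryRecord",
    "TopSequence",
    "propose_move",
    "metropolis_accept",
    "run_trajectory",
    "run_evolution",
    "extract_top_sequences",
    "STAGE1_TEMPERATURES",
]

STAGE1_TEMPERATURES = (0.3, 0.03, 0.003)


@dataclass(frozen=True)
class EvolutionConfig:
    """Parameters of one in silico evolution run.

    ``allowed_moves`` is either ``"all"`` (any position, any replacement
    symbol) or an explicit collection of :class:`Mutation`; in the explicit
    case reversions to the wild-type symbol at those positions are always
    permitted so the chain remains irreducible.
    """

    n_trajectories: int = 2000
    n_steps: int = 500
    trust_radius: int = 2
    temperature: float = 0.03
    allowed_moves: object = "all"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trajectories < 1 or self.n_steps < 1:
            raise ValueError("n_trajectories and n_steps must be positive")
        if self.trust_radius < 0:
            raise ValueError("trust_radius must be non-negative")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.allowed_moves != "all":
            moves = tuple(self.allowed_moves)
            if not moves:
                raise ValueError("allowed_moves must be 'all' or a non-empty set")
            object.__setattr__(self, "allowed_moves", moves)

    def validate_against(self, model: PottsModel) -> None:
        if self.trust_radius > model.L:
            raise ValueError(
                f"trust_radius {self.trust_radius} exceeds model length {model.L}"
            )
        if self.allowed_moves != "all":
            for m in self.allowed_moves:
                model.validate_variant(VariantGenotype((m,)))


@dataclass
class TrajectoryRecord:
    """One Markov chain: visited states, scores and acceptance flags.

    ``states`` holds the integer-encoded sequence after each step, including
    the initial wild type (shape ``(n_steps + 1, L)``); ``scores`` are the
    predicted-fitness differences to the wild type; ``accepted[k]`` says
    whether proposal ``k`` was taken.
    """

    states: np.ndarray
    scores: np.ndarray
    accepted: np.ndarray
    wt_encoded: np.ndarray
    best_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.best_index = int(np.argmax(self.scores))  # first max wins

    @property
    def best_state(self) -> np.ndarray:
        return self.states[self.best_index]

    @property
    def best_score(self) -> float:
        return float(self.scores[self.best_index])

    @property
    def n_steps(self) -> int:
        return len(self.accepted)

    def hamming_distances(self) -> np.ndarray:
        return (self.states != self.wt_encoded[None, :]).sum(axis=1)

    def best_variant(self, model: PottsModel) -> VariantGenotype:
        return _variant_from_encoded(model, self.best_state)


def _variant_from_encoded(model: PottsModel, state: np.ndarray) -> VariantGenotype:
    wt = model.wt_encoded()
    muts = tuple(
        Mutation(int(i) + 1, model.alphabet[wt[i]], model.alphabet[state[i]])
        for i in np.nonzero(state != wt)[0]
    )
    return VariantGenotype(muts)


class _MoveTable:
    """Precomputed proposal table: allowed replacement symbols per position."""

    def __init__(self, model: PottsModel, config: EvolutionConfig):
        wt = model.wt_encoded()
        q = model.q
        if config.allowed_moves == "all":
            self.positions = np.arange(model.L)
            # at every position all q symbols are in play (current one is
            # excluded at proposal time)
            self.symbols = [np.arange(q) for _ in range(model.L)]
            self.pos_lookup = {int(p): k for k, p in enumerate(self.positions)}
        else:
            per_pos: dict[int, set[int]] = {}
            for m in config.allowed_moves:
                i = m.position - 1
                per_pos.setdefault(i, {int(wt[i])}).add(model._index[m.mut_symbol])
            self.positions = np.array(sorted(per_pos), dtype=np.int64)
            self.symbols = [np.array(sorted(per_pos[int(i)])) for i in self.positions]
            self.pos_lookup = {int(p): k for k, p in enumerate(self.positions)}


def metropolis_accept(delta_score: float, temperature: float, rng) -> bool:
    """Metropolis rule: accept with probability min(1, exp(delta / T))."""
    if not math.isfinite(delta_score):
        raise ValueError(f"non-finite score difference: {delta_score}")
    if not temperature > 0:
        raise ValueError("temperature must be positive")
    if delta_score >= 0:
        return True
    x = delta_score / temperature
    if x < -745.0:  # exp underflows to 0
        return False
    return bool(rng.random() < math.exp(x))


def _propose_encoded(
    state: np.ndarray,
    wt: np.ndarray,
    table: _MoveTable,
    trust_radius: int,
    rng,
) -> tuple[int, int] | None:
    """Draw one (position, new_symbol) proposal; None means 'stay put'."""
    if trust_radius == 0:
        return None
    mutated = np.nonzero(state != wt)[0]
    at_boundary = len(mutated) >= trust_radius
    if at_boundary:
        candidates = [i for i in mutated if int(i) in table.pos_lookup]
        if not candidates:
            return None
        i = int(candidates[rng.integers(len(candidates))])
    else:
        i = int(table.positions[rng.integers(len(table.positions))])
    syms = table.symbols[table.pos_lookup[i]]
    choices = syms[syms != state[i]]
    if len(choices) == 0:
        return None
    return i, int(choices[rng.integers(len(choices))])


def propose_move(
    model: PottsModel, state: VariantGenotype, config: EvolutionConfig, rng
) -> VariantGenotype:
    """Propose a single-exchange neighbour of ``state`` inside the trust radius."""
    config.validate_against(model)
    model.validate_variant(state)
    if state.n_mutations > config.trust_radius:
        raise ValueError(
            f"state at Hamming distance {state.n_mutations} exceeds "
            f"trust radius {config.trust_radius}"
        )
    wt = model.wt_encoded()
    enc = model.encode(state.apply_to(model.wt_sequence))
    table = _MoveTable(model, config)
    move = _propose_encoded(enc, wt, table, config.trust_radius, rng)
    if move is None:
        return state
    i, b = move
    enc = enc.copy()
    enc[i] = b
    return _variant_from_encoded(model, enc)


def _delta_score(model: PottsModel, state: np.ndarray, i: int, b: int) -> float:
    """Score change for replacing symbol at position ``i`` by ``b`` (O(L))."""
    a = state[i]
    d = model.h[i, b] - model.h[i, a]
    cols = np.arange(model.L)
    d += (model.J[i, cols, b, state] - model.J[i, cols, a, state]).sum()
    return float(d)


def run_trajectory(
    model: PottsModel, config: EvolutionConfig, rng=None
) -> TrajectoryRecord:
    """Run one Metropolis-Hastings chain of ``config.n_steps`` proposals."""
    config.validate_against(model)
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    wt = model.wt_encoded()
    table = _MoveTable(model, config)

    n = config.n_steps
    states = np.empty((n + 1, model.L), dtype=np.int64)
    scores = np.zeros(n + 1)
    accepted = np.zeros(n, dtype=bool)
    state = wt.copy()
    score = 0.0
    states[0] = state

    for k in range(n):
        move = _propose_encoded(state, wt, table, config.trust_radius, rng)
        if move is not None:
            i, b = move
            delta = _delta_score(model, state, i, b)
            if metropolis_accept(delta, config.temperature, rng):
                state[i] = b
                score += delta
                accepted[k] = True
        states[k + 1] = state
        scores[k + 1] = score

    rec = TrajectoryRecord(states=states, scores=scores, accepted=accepted, wt_encoded=wt)
    assert rec.hamming_distances().max(initial=0) <= config.trust_radius
    return rec


def _run_one(model: PottsModel, config: EvolutionConfig, seed_seq) -> TrajectoryRecord:
    return run_trajectory(model, config, rng=np.random.default_rng(seed_seq))


def run_evolution(
    model: PottsModel, config: EvolutionConfig, n_jobs: int = 1
) -> list[TrajectoryRecord]:
    """Run ``config.n_trajectories`` independent chains.

    Per-trajectory RNG streams are spawned from the master seed, so results
    are identical regardless of ``n_jobs`` and of how many trajectories run.
    """
    config.validate_against(model)
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_trajectories)
    if n_jobs == 1:
        return [_run_one(model, config, s) for s in seeds]
    from joblib import Parallel, delayed

    return Parallel(n_jobs=n_jobs)(delayed(_run_one)(model, config, s) for s in seeds)


@dataclass(frozen=True)
class TopSequence:
    """A ranked sequence extracted from trajectories."""

    sequence: str
    score: float
    mutations: tuple[Mutation, ...]
    trajectory_index: int
    step_index: int

    @property
    def label(self) -> str:
        return "+".join(m.label for m in self.mutations) if self.mutations else "WT"


def extract_top_sequences(
    model: PottsModel,
    trajectories: list[TrajectoryRecord],
    n_top: int,
    mode: str = "per-trajectory-best",
) -> list[TopSequence]:
    """Rank the highest-scoring visited sequences.

    ``mode="per-trajectory-best"`` considers each chain's best state only
    (the published protocol); ``mode="global-top"`` ranks every visited state.
    Duplicates collapse to their first visit; ties are broken by
    first-visited order, then by lexicographic mutation label.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if mode not in ("per-trajectory-best", "global-top"):
        raise ValueError(f"unknown mode {mode!r}")

    seen: dict[tuple, TopSequence] = {}

    def _consider(t_idx: int, s_idx: int, state: np.ndarray, score: float) -> None:
        key = tuple(state)
        if key not in seen:
            seen[key] = TopSequence(
                sequence=model.decode(state),
                score=float(score),
                mutations=_variant_from_encoded(model, state).mutations,
                trajectory_index=t_idx,
                step_index=s_idx,
            )

    for t_idx, rec in enumerate(trajectories):
        if mode == "per-trajectory-best":
            _consider(t_idx, rec.best_index, rec.best_state, rec.best_score)
        else:
            # only accepted (newly visited) states plus the start can be new
            new_idx = np.concatenate(([0], 1 + np.nonzero(rec.accepted)[0]))
            for s_idx in new_idx:
                _consider(t_idx, int(s_idx), rec.states[s_idx], rec.scores[s_idx])

    ranked = sorted(
        seen.values(),
        key=lambda t: (-t.score, t.trajectory_index, t.step_index, t.label),
    )
    if n_top > len(ranked):
        warnings.warn(
            f"requested n_top={n_top} but only {len(ranked)} distinct states visited",
            stacklevel=2,
        )
    return ranked[:n_top]
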