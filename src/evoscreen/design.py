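"""Combinatorial library design from in silico evolution output.

The two-stage protocol: a first broad run (trust radius 2, three
temperatures) nominates positions of interest; the 30 most frequently
occurring replacements among the top-scoring sequences seed a second,
move-restricted run at trust radius 3; the replacements that co-occur most
frequently among its top sequences are recommended for the combinatorial
library.  Enumerating all subsets of k selected exchanges gives a 2^k-member
library (k = 5 -> 32 variants; dropping one exchange -> 16), each member
tagged with a distinct random DNA barcode.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evolve import (
    STAGE1_TEMPERATURES,
    EvolutionConfig,
    TopSequence,
    run_evolution,
)
from .potts import (
    IndependentModel,
    Mutation,
    PottsModel,
    VariantGenotype,
    epistatic_score,
    independent_score,
)

__all__ = [
    "ExchangeFrequencyTable",
    "CombinatorialLibrary",
    "DesignResult",
    "count_exchanges",
    "select_top_replacements",
    "select_cooccurring",
    "recommend_library",
    "enumerate_library",
    "assign_barcodes",
    "run_two_stage_design",
]


@dataclass
class ExchangeFrequencyTable:
    """Occurrence and co-occurrence tallies of exchanges among top sequences."""

    singles: dict[Mutation, int]
    pairs: dict[frozenset, int]
    n_sequences: int

    def __post_init__(self) -> None:
        for pair, c in self.pairs.items():
            a, b = tuple(pair)
            if c > min(self.singles.get(a, 0), self.singles.get(b, 0)):
                raise ValueError(f"pair count for {a.label},{b.label} exceeds member counts")

    def occurrence(self, m: Mutation) -> int:
        return self.singles.get(m, 0)

    def cooccurrence(self, a: Mutation, b: Mutation) -> int:
        return self.pairs.get(frozenset((a, b)), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"exchange": m.label, "position": m.position, "count": c}
            for m, c in sorted(self.singles.items(), key=lambda kv: (-kv[1], kv[0].position))
        ]
        return pd.DataFrame(rows, columns=["exchange", "position", "count"])


def _mutations_of(seq, wt: str) -> tuple[Mutation, ...]:
    if isinstance(seq, VariantGenotype):
        return seq.mutations
    if isinstance(seq, TopSequence):
        return seq.mutations
    if len(seq) != len(wt):
        raise ValueError(f"sequence length {len(seq)} != wild type length {len(wt)}")
    return tuple(
        Mutation(i, w, s) for i, (w, s) in enumerate(zip(wt, seq), start=1) if w != s
    )


def count_exchanges(top_sequences, wt: str) -> ExchangeFrequencyTable:
    """Tally single exchanges and unordered pairs within each top sequence.

    ``top_sequences`` may contain plain sequences, :class:`TopSequence`
    entries or :class:`VariantGenotype` objects.
    """
    singles: dict[Mutation, int] = {}
    pairs: dict[frozenset, int] = {}
    n = 0
    for seq in top_sequences:
        muts = _mutations_of(seq, wt)
        n += 1
        for m in muts:
            singles[m] = singles.get(m, 0) + 1
        for a, b in itertools.combinations(muts, 2):
            key = frozenset((a, b))
            pairs[key] = pairs.get(key, 0) + 1
    return ExchangeFrequencyTable(singles=singles, pairs=pairs, n_sequences=n)


def _tie_key(m: Mutation, model: PottsModel | None):
    score = epistatic_score(model, VariantGenotype((m,))) if model is not None else 0.0
    return (-score, m.position, m.mut_symbol)


def select_top_replacements(
    table: ExchangeFrequencyTable, n: int = 30, model: PottsModel | None = None
) -> list[Mutation]:
    """The ``n`` most frequently occurring exchanges.

    Ties are broken by higher single-mutant epistatic score (when a model is
    supplied) and then by position order.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(table.singles, key=lambda m: (-table.singles[m], *_tie_key(m, model)))
    if len(ranked) < n:
        warnings.warn(
            f"only {len(ranked)} distinct exchanges observed (requested {n})",
            stacklevel=2,
        )
    return ranked[:n]


def select_cooccurring(
    table: ExchangeFrequencyTable, k: int, model: PottsModel | None = None
) -> list[Mutation]:
    """Greedy set of ``k`` exchanges maximizing summed pairwise co-occurrence.

    The final published choice also weighed predicted fitness of the
    combinatorial variants qualitatively; this function returns a ranked
    recommendation, not an automated final decision.  With no co-occurrence
    signal at all it falls back to plain occurrence ranking.
    """
    available = list(table.singles)
    if k > len(available):
        raise ValueError(f"k={k} exceeds {len(available)} available exchanges")
    if not table.pairs or all(c == 0 for c in table.pairs.values()):
        warnings.warn("no co-occurrence signal; falling back to occurrence ranking",
                      stacklevel=2)
        return select_top_replacements(table, k, model=model)

    def order_key(m: Mutation):
        return (-table.singles[m], *_tie_key(m, model))

    best_pair = min(
        table.pairs,
        key=lambda p: (-table.pairs[p], _pair_order(p, order_key)),
    )
    chosen = sorted(best_pair, key=order_key)
    while len(chosen) < k:
        rest = [m for m in available if m not in chosen]
        rest.sort(key=lambda m: (-sum(table.cooccurrence(m, c) for c in chosen), *order_key(m)))
        chosen.append(rest[0])
    return sorted(chosen, key=lambda m: m.position)


def _pair_order(pair: frozenset, order_key):
    # stable deterministic ordering helper for pair ties
    a, b = sorted(pair, key=order_key)
    ka, kb = order_key(a), order_key(b)
    return [x for x in (*ka, *kb)]


@dataclass
class CombinatorialLibrary:
    """All 2^k combinations of k selected exchanges, scored and barcoded."""

    exchanges: tuple[Mutation, ...]
    members: tuple[VariantGenotype, ...]
    epistatic_scores: tuple[float, ...]
    independent_scores: tuple[float, ...] | None = None
    min_barcode_distance: int | None = None

    @property
    def size(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for idx, (v, e) in enumerate(zip(self.members, self.epistatic_scores)):
            rows.append(
                {
                    "label": v.label,
                    "n_mutations": v.n_mutations,
                    "mutations": ";".join(m.label for m in v.mutations),
                    "epistatic_score": e,
                    "independent_score": (
                        self.independent_scores[idx]
                        if self.independent_scores is not None
                        else np.nan
                    ),
                    "barcode": v.barcode or "",
                }
            )
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def enumerate_library(
    exchanges,
    model: PottsModel,
    imodel: IndependentModel | None = None,
) -> CombinatorialLibrary:
    """Score every subset of the selected exchanges (wild type included)."""
    exchanges = tuple(sorted(exchanges, key=lambda m: m.position))
    positions = [m.position for m in exchanges]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate positions among exchanges: {positions}")
    k = len(exchanges)
    if k > 16:
        raise ValueError(f"k={k} would enumerate 2^{k} members; limit is 16")
    members, e_scores, i_scores = [], [], []
    for r in range(k + 1):
        for combo in itertools.combinations(exchanges, r):
            v = VariantGenotype(combo)
            members.append(v)
            e_scores.append(epistatic_score(model, v))
            if imodel is not None:
                i_scores.append(independent_score(imodel, v))
    return CombinatorialLibrary(
        exchanges=exchanges,
        members=tuple(members),
        epistatic_scores=tuple(e_scores),
        independent_scores=tuple(i_scores) if imodel is not None else None,
    )


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def assign_barcodes(
    library: CombinatorialLibrary,
    length: int = 20,
    min_distance: int = 5,
    rng_seed: int = 0,
    max_attempts_per_member: int = 10_000,
) -> CombinatorialLibrary:
    """Attach random distinct DNA barcodes with a pairwise-distance floor.

    Default length 20 nt; the distance floor of 5 tolerates the 20% matching
    error rate used when counting reads downstream.
    """
    n = library.size
    if min_distance > length:
        raise ValueError("min_distance cannot exceed barcode length")
    if 4**length <= n:
        raise ValueError("barcode space too small for member count")
    rng = np.random.default_rng(rng_seed)
    barcodes: list[str] = []
    attempts = 0
    while len(barcodes) < n:
        if attempts > max_attempts_per_member * n:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at "
                f"min distance {min_distance}"
            )
        attempts += 1
        cand = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
        if all(_hamming(cand, b) >= max(min_distance, 1) for b in barcodes):
            barcodes.append(cand)
    members = tuple(
        VariantGenotype(v.mutations, label=v.label, barcode=bc)
        for v, bc in zip(library.members, barcodes)
    )
    return CombinatorialLibrary(
        exchanges=library.exchanges,
        members=members,
        epistatic_scores=library.epistatic_scores,
        independent_scores=library.independent_scores,
        min_barcode_distance=min_distance,
    )


def recommend_library(
    table: ExchangeFrequencyTable,
    model: PottsModel,
    k: int,
    pool_size: int | None = None,
) -> list[Mutation]:
    """Final library recommendation: frequency-ranked, fitness-decided.

    Mirrors the published decision: occurrence and co-occurrence frequencies
    shortlist candidate exchanges, and the predicted fitness of the
    combinatorial variants decides among them.  The candidate pool is the
    ``pool_size`` (default 2k) most frequently occurring exchanges plus the
    greedy co-occurrence set; the returned set is the k-subset of the pool
    whose full combination has the highest epistatic score (ties broken by
    higher summed co-occurrence, then position order).
    """
    if pool_size is None:
        pool_size = 2 * k
    pool = list(select_top_replacements(table, min(pool_size, len(table.singles)),
                                        model=model))
    for m in select_cooccurring(table, min(k, len(table.singles)), model=model):
        if m not in pool:
            pool.append(m)
    # distinct positions: keep the best-ranked exchange per position
    by_pos: dict[int, Mutation] = {}
    for m in pool:
        by_pos.setdefault(m.position, m)
    pool = list(by_pos.values())
    if len(pool) < k:
        raise ValueError(f"only {len(pool)} candidate positions for k={k}")

    def _combo_key(combo):
        score = epistatic_score(model, VariantGenotype(combo))
        cooc = sum(
            table.cooccurrence(a, b) for a, b in itertools.combinations(combo, 2)
        )
        positions = tuple(sorted(m.position for m in combo))
        return (-score, -cooc, positions)

    best = min(itertools.combinations(pool, k), key=_combo_key)
    return sorted(best, key=lambda m: m.position)


def _top_trajectory_bests(model, trajectories, top_fraction: float, floor: int = 20):
    """Highest-scoring per-trajectory best states, duplicates retained.

    Occurrence/co-occurrence frequencies are counted over chains, so a state
    found independently by many chains must be counted once per chain —
    unlike :func:`extract_top_sequences`, which collapses duplicates for
    ranked output.
    """
    from .evolve import _variant_from_encoded

    order = sorted(
        range(len(trajectories)), key=lambda t: -trajectories[t].best_score
    )
    n_top = min(len(order), max(floor, int(top_fraction * len(order))))
    return [
        _variant_from_encoded(model, trajectories[t].best_state)
        for t in order[:n_top]
    ]


@dataclass
class DesignResult:
    """Everything the two-stage design pipeline produced.

    ``selected`` is the final recommendation (frequency-shortlisted,
    decided by predicted combinatorial fitness); ``cooccurrence_selection``
    is the intermediate greedy co-occurrence pick.
    """

    stage1_table: ExchangeFrequencyTable
    stage1_replacements: list[Mutation]
    stage2_table: ExchangeFrequencyTable
    cooccurrence_selection: list[Mutation]
    selected: list[Mutation]


def run_two_stage_design(
    model: PottsModel,
    k: int = 5,
    n_replacements: int = 30,
    rng_seed: int = 0,
    stage1_trajectories: int = 2000,
    stage1_steps: int = 500,
    stage1_trust_radius: int = 2,
    stage1_temperatures=STAGE1_TEMPERATURES,
    stage2_trajectories: int = 750,
    stage2_steps: int = 500,
    stage2_trust_radius: int = 3,
    stage2_temperature: float = 0.03,
    stage1_top_fraction: float = 1.0,
    stage2_top_fraction: float = 0.25,
    n_jobs: int = 1,
) -> DesignResult:
    """Full design protocol: broad run, replacement shortlist, restricted run.

    ``stage1_trajectories`` is the total across the temperature grid (split
    evenly).  The ``*_top_fraction`` parameters control how many
    per-trajectory-best sequences count as "highest scoring" in each stage:
    stage 1 casts a wide position-nomination net (default: every
    trajectory's best), stage 2 keeps only the top quarter, where the
    co-occurrence signal concentrates.
    """
    seeds = np.random.SeedSequence(rng_seed).generate_state(len(stage1_temperatures) + 1)
    per_temp = max(1, stage1_trajectories // len(stage1_temperatures))

    stage1_tops: list[VariantGenotype] = []
    for temp, seed in zip(stage1_temperatures, seeds):
        cfg = EvolutionConfig(
            n_trajectories=per_temp,
            n_steps=stage1_steps,
            trust_radius=stage1_trust_radius,
            temperature=temp,
            rng_seed=int(seed % (2**31)),
        )
        trajs = run_evolution(model, cfg, n_jobs=n_jobs)
        stage1_tops.extend(_top_trajectory_bests(model, trajs, stage1_top_fraction))

    stage1_table = count_exchanges(stage1_tops, model.wt_sequence)
    shortlist = select_top_replacements(stage1_table, n=n_replacements, model=model)

    cfg2 = EvolutionConfig(
        n_trajectories=stage2_trajectories,
        n_steps=stage2_steps,
        trust_radius=stage2_trust_radius,
        temperature=stage2_temperature,
        allowed_moves=tuple(shortlist),
        rng_seed=int(seeds[-1] % (2**31)),
    )
    trajs2 = run_evolution(model, cfg2, n_jobs=n_jobs)
    stage2_tops = _top_trajectory_bests(model, trajs2, stage2_top_fraction)
    stage2_table = count_exchanges(stage2_tops, model.wt_sequence)
    cooc = select_cooccurring(stage2_table, k=k, model=model)
    selected = recommend_library(stage2_table, model, k=k)
    return DesignResult(
        stage1_table=stage1_table,
        stage1_replacements=shortlist,
        stage2_table=stage2_table,
        cooccurrence_selection=cooc,
        selected=selected,
    )
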