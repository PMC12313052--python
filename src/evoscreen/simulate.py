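"""Synthetic-data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here: Potts
landscapes with planted beneficial exchanges and planted epistatic (rescue)
pairs, multinomial read-count time courses of a pooled competition, barcoded
amplicon FASTQ reads with sequencing errors, and OD / NADH-assay traces.
Every generator is seed-deterministic and emits its ground truth alongside
the data, so downstream recovery tests never need wet-lab inputs.

The default competition scenario mirrors the screen being emulated: a
16-member variant pool grown in 4 replicate cultivations under 2 gas
conditions, sampled at generations 0, 2, 4, 6, 8 and 10 at a sequencing
depth of 10^6 reads per sample, with true fitness values forming three
separated groups (wild-type-like, intermediate, strongly depleted).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counting import DOWNSTREAM_ANCHOR, UPSTREAM_ANCHOR, BarcodeLibrary
from .growth import ODSeries
from .potts import IndependentModel, Mutation, PottsModel, PROTEIN_ALPHABET
from .screen import CountMatrix

__all__ = [
    "SimulationScenario",
    "make_potts",
    "three_group_fitness",
    "simulate_competition",
    "simulate_fastq",
    "simulate_od",
    "simulate_assay",
]

GENERATIONS = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
CONDITIONS = ("5pctCO2_0pctO2", "5pctCO2_20pctO2")


@dataclass
class SimulationScenario:
    """Stated world of one simulation run.

    Landscape: length ``L`` over ``alphabet``; background substitution
    effects ~ Normal(``field_loc``, ``field_scale``), centered well below
    zero because the bulk of substitutions in a conserved protein is
    deleterious; sparse coupling blocks of density ``coupling_density``
    and scale ``coupling_scale``; ``n_planted`` strongly beneficial
    exchanges with field boosts drawn uniformly from
    ``planted_boost_range`` (default 2.6-4.7, the scale of the strongest
    single-replacement scores such landscape models report);
    ``n_decoys`` decoy exchanges with effects drawn from
    ``decoy_boost_range`` (default -1.0 to +0.5: mostly mildly deleterious
    with a weak beneficial tail, as real landscape models predict for the
    bulk of substitutions).  The planted exchanges are mutually compatible:
    every planted pair carries a positive coupling of size
    ``planted_coupling``, so each double mutant scores above the sum of its
    singles by that margin (the rescue-epistasis motif).

    Pool/sequencing: ``n_variants`` pool members, ``depth`` reads per
    sample, per-base sequencing ``error_rate``, samples at ``generations``
    for ``replicates`` replicate cultivations under ``conditions``.
    """

    rng_seed: int = 0
    # landscape
    L: int = 60
    alphabet: str = PROTEIN_ALPHABET
    field_loc: float = -2.0
    field_scale: float = 0.5
    coupling_density: float = 0.05
    coupling_scale: float = 0.2
    n_planted: int = 5
    planted_boost_range: tuple = (2.6, 4.7)
    n_decoys: int = 50
    decoy_boost_range: tuple = (-1.0, 0.5)
    planted_coupling: float = 1.0
    # pool / sequencing
    n_variants: int = 16
    depth: int = 1_000_000
    error_rate: float = 0.0
    generations: tuple = GENERATIONS
    replicates: int = 4
    conditions: tuple = CONDITIONS
    replicate_jitter_concentration: float = 2000.0
    condition_fitness_sd: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_density <= 1.0:
            raise ValueError("coupling_density must be in [0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 <= self.error_rate < 0.75:
            raise ValueError("error_rate must be in [0, 0.75)")
        if self.n_planted + self.n_decoys > self.L:
            raise ValueError("more planted+decoy exchanges than positions")
        if any(g < 0 for g in self.generations):
            raise ValueError("generations must be non-negative")


def make_potts(scenario: SimulationScenario, rng=None):
    """Random landscape with planted signal.

    Returns ``(model, imodel, planted, decoys, planted_pairs)`` where
    ``planted`` and ``decoys`` are lists of :class:`Mutation` and
    ``planted_pairs`` lists every planted pair; each such double mutant
    scores above the sum of its singles by ``planted_coupling`` (mutual
    compatibility / rescue-epistasis motif).  Planted positions carry no
    random couplings, so the planted exchanges are exactly the top-ranked
    single replacements.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    L, q = scenario.L, len(scenario.alphabet)
    wt_idx = rng.integers(0, q, size=L)
    wt = "".join(scenario.alphabet[i] for i in wt_idx)

    # bulk substitutions are deleterious (field_loc < 0), as landscape
    # models of conserved proteins predict; decoys supply the weak
    # near-neutral tail and stay below the planted range
    h = rng.normal(scenario.field_loc, scenario.field_scale, size=(L, q))
    h = np.clip(h, None, max(scenario.decoy_boost_range) * 0.6)
    h[np.arange(L), wt_idx] = 0.0  # wild type is the reference state

    special_pos = rng.choice(L, size=scenario.n_planted + scenario.n_decoys, replace=False)
    planted_pos = special_pos[: scenario.n_planted]
    decoy_pos = special_pos[scenario.n_planted :]

    def _plant(pos: int, boost: float) -> Mutation:
        choices = [a for a in range(q) if a != wt_idx[pos]]
        a = int(rng.choice(choices))
        h[pos, a] = boost
        return Mutation(int(pos) + 1, wt[pos], scenario.alphabet[a])

    planted = [
        _plant(p, float(rng.uniform(*scenario.planted_boost_range)))
        for p in planted_pos
    ]
    decoys = [
        _plant(p, float(rng.uniform(*scenario.decoy_boost_range))) for p in decoy_pos
    ]

    J = np.zeros((L, L, q, q))
    if scenario.coupling_density > 0 and scenario.coupling_scale > 0:
        allowed = np.setdiff1d(np.arange(L), planted_pos)
        for ii, i in enumerate(allowed):
            for j in allowed[ii + 1 :]:
                if rng.random() < scenario.coupling_density:
                    block = rng.normal(0.0, scenario.coupling_scale, size=(q, q))
                    J[i, j] = block
                    J[j, i] = block.T

    planted_pairs = []
    for ia in range(len(planted)):
        for ib in range(ia + 1, len(planted)):
            ma, mb = planted[ia], planted[ib]
            i, j = ma.position - 1, mb.position - 1
            a = scenario.alphabet.index(ma.mut_symbol)
            b = scenario.alphabet.index(mb.mut_symbol)
            J[i, j, a, b] += scenario.planted_coupling
            J[j, i, b, a] += scenario.planted_coupling
            planted_pairs.append((ma, mb))

    model = PottsModel(h=h, J=J, wt_sequence=wt, alphabet=scenario.alphabet)
    imodel = IndependentModel(fields=h.copy(), wt_sequence=wt, alphabet=scenario.alphabet)
    return model, imodel, planted, decoys, planted_pairs


def three_group_fitness(n_variants: int = 16, rng=None) -> np.ndarray:
    """True fitness values in three separated groups (log2/generation).

    Group centers 0.0 (wild-type-like), -0.4 (intermediate) and -0.9
    (strongly depleted) with 0.03 s.d. within-group jitter; no variant beats
    the wild type, matching the observed screen structure.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    centers = np.array([0.0, -0.4, -0.9])
    sizes = [n_variants - 2 * (n_variants // 3), n_variants // 3, n_variants // 3]
    f = np.concatenate([np.full(s, c) for c, s in zip(centers, sizes)])
    f = f + rng.normal(0.0, 0.03, size=n_variants)
    f[0] = 0.0  # wild type is the reference member
    return f


def simulate_competition(
    scenario: SimulationScenario,
    true_fitness: np.ndarray | dict | None = None,
    variant_labels: list[str] | None = None,
    rng=None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Multinomial read counts of a pooled competition with known fitness.

    Expected frequencies follow exponential selection,
    ``x_i(g) proportional to x_i(0) * 2**(f_i * g)``; counts are multinomial
    at the configured depth per sample, and each replicate starts from a
    jittered copy of the initial pool.  Returns the count matrix and a truth
    table (variant, condition, true_fitness, initial_frequency).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.rng_seed)
    n = scenario.n_variants
    if variant_labels is None:
        variant_labels = [f"variant{i:02d}" if i else "WT" for i in range(n)]
    if true_fitness is None:
        base = three_group_fitness(n, rng)
        fitness_by_condition = {scenario.conditions[0]: base}
        for cond in scenario.conditions[1:]:
            fitness_by_condition[cond] = base + rng.normal(
                0.0, scenario.condition_fitness_sd, size=n
            )
    elif isinstance(true_fitness, dict):
        fitness_by_condition = {c: np.asarray(true_fitness[c], dtype=float)
                                for c in scenario.conditions}
    else:
        true_fitness = np.asarray(true_fitness, dtype=float)
        fitness_by_condition = {c: true_fitness for c in scenario.conditions}

    base_freq = rng.dirichlet(np.full(n, 50.0))  # near-uniform starting pool

    columns, meta_rows = [], []
    data = {}
    truth_rows = []
    for cond in scenario.conditions:
        f = fitness_by_condition[cond]
        for v, tf, x0 in zip(variant_labels, f, base_freq):
            truth_rows.append(
                {"variant": v, "condition": cond, "true_fitness": float(tf),
                 "initial_frequency": float(x0)}
            )
        for rep in range(1, scenario.replicates + 1):
            rep_freq = rng.dirichlet(base_freq * scenario.replicate_jitter_concentration)
            for g in scenario.generations:
                w = rep_freq * np.exp2(f * g)
                p = w / w.sum()
                counts = rng.multinomial(scenario.depth, p)
                sample = f"{cond}_r{rep}_g{g:g}"
                columns.append(sample)
                data[sample] = counts
                meta_rows.append(
                    {"sample": sample, "condition": cond, "replicate": rep,
                     "generation": g}
                )

    counts_df = pd.DataFrame(data, index=variant_labels, columns=columns)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    truth = pd.DataFrame(truth_rows)  # true fitness is uncentered ground truth
    return CountMatrix(counts=counts_df, samples=samples), truth


def simulate_fastq(
    counts: CountMatrix,
    lib: BarcodeLibrary,
    out_dir,
    error_rate: float = 0.0,
    rng=None,
    gzip_output: bool = False,
    max_phase_shift: int = 3,
) -> tuple[dict, dict]:
    """Emit one FASTQ file per sample from a count matrix.

    Each read is a random 0-``max_phase_shift`` nt phasing prefix, the
    upstream anchor, the variant's barcode and the downstream anchor, with
    independent per-base substitution errors at ``error_rate``.  Returns
    ``(paths, truth)`` where ``truth[sample]`` lists the generating barcode
    id of every emitted read in order.
    """
    if not 0.0 <= error_rate < 0.75:
        raise ValueError("error_rate must be in [0, 0.75)")
    if rng is None:
        rng = np.random.default_rng(0)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    paths, truth = {}, {}
    matched = counts.matched()
    for sample in matched.columns:
        suffix = ".fastq.gz" if gzip_output else ".fastq"
        path = out_dir / f"{sample}{suffix}"
        opener = gzip.open if gzip_output else open
        origins = []
        with opener(path, "wt") as fh:
            for variant, c in matched[sample].items():
                bc = lib.barcodes[variant]
                for _ in range(int(c)):
                    shift = int(rng.integers(0, max_phase_shift + 1))
                    prefix = "".join(
                        "ACGT"[i] for i in rng.integers(0, 4, size=shift)
                    )
                    seq = prefix + lib.upstream + bc + lib.downstream
                    if error_rate > 0:
                        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                        hit = rng.random(len(arr)) < error_rate
                        if hit.any():
                            repl = alphabet[rng.integers(0, 4, size=int(hit.sum()))]
                            arr[hit] = repl
                        seq = arr.tobytes().decode()
                    origins.append(variant)
                    fh.write(f"@{sample}:{len(origins)}\n{seq}\n+\n{'I' * len(seq)}\n")
        paths[sample] = path
        truth[sample] = origins
    return paths, truth


def simulate_od(
    growth_rate: float,
    noise_sd: float = 0.0,
    duration: float = 48.0,
    interval: float = 0.5,
    od0: float = 0.05,
    rng=None,
    metadata: dict | None = None,
) -> ODSeries:
    """Exponential OD time course with multiplicative log-normal noise."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(0.0, duration + 1e-9, interval)
    od = od0 * np.exp(growth_rate * t)
    if noise_sd > 0:
        od = od * np.exp(rng.normal(0.0, noise_sd, size=len(t)))
    return ODSeries(time=t, od=od, metadata=metadata or {})


def simulate_assay(
    k_app: float,
    protein_conc: float = 500e-9,
    beta: float = 1569.0,
    a0: float = 1.0,
    duration_s: float = 900.0,
    interval_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Linear NADH-depletion absorbance trace for a known k_app.

    Inverse of the k_app conversion: concentration slope
    ``-k_app * protein_conc`` (M/s), absorbance slope ``2 * beta`` times
    that.  Returns (time in s, A340).
    """
    t = np.arange(0.0, duration_s + 1e-9, interval_s)
    conc_slope = -k_app * protein_conc
    abs_slope = conc_slope * 2.0 * beta
    return t, a0 + abs_slope * t
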