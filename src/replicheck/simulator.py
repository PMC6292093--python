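"""Synthetic replicate datasets with known truth, plus experiment drivers.

The generator mirrors the observation model used for inference: one
diploid genotype per distinct source is drawn under Hardy–Weinberg
equilibrium at each site's B-allele frequency, per-sample read depths are
Poisson, and each read reports allele B with probability ``e``, ``0.5`` or
``1 - e`` according to the source genotype. Optionally a chosen sample is
contaminated at a fraction of sites by an independently drawn genotype.

The ``run_*`` drivers reproduce the four simulation designs used to
characterize the method: a depth-by-MAF accuracy grid, a sweep over the
number of sites ``L``, a contamination sensitivity study, and an
unequal-depth study. They emit tidy per-replicate tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .partition_model import (
    ReplicateDataset,
    SourceVector,
    joint_posterior,
    source_vector_classes,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_site_frequencies",
    "simulate_source_genotypes",
    "inject_contamination",
    "simulate_allele_depths",
    "simulate_dataset",
    "run_accuracy_grid",
    "run_l_sweep",
    "run_sensitivity",
    "run_unequal_depths",
    "summarize_cells",
]

#: Base-pair spacing between consecutive synthetic sites; comfortably
#: beyond the default 20 kb minimum-distance filter.
_SITE_SPACING = 25_000

_SIM_CHROM = "sim1"


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one synthetic replicate dataset.

    ``lambda_per_sample`` holds one Poisson mean depth per sample; use
    :meth:`create` to broadcast a scalar. ``contamination`` is an optional
    ``(sample_index, fraction)`` pair: the given sample's reads at
    ``round(fraction * L)`` sites come from a foreign genotype.
    """

    true_S: SourceVector
    L: int
    maf_window: tuple[float, float]
    lambda_per_sample: tuple[float, ...]
    error_rate: float = 0.01
    contamination: tuple[int, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be positive, got {self.L}")
        lo, hi = self.maf_window
        if not 0.0 <= lo < hi <= 0.5:
            raise ValueError(
                f"maf_window must satisfy 0 <= lo < hi <= 0.5, got {self.maf_window}"
            )
        if len(self.lambda_per_sample) != self.true_S.k:
            raise ValueError(
                f"need one lambda per sample ({self.true_S.k}), got "
                f"{len(self.lambda_per_sample)}"
            )
        if any(lam <= 0 for lam in self.lambda_per_sample):
            raise ValueError("all mean depths must be positive")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError(
                f"error_rate must lie in (0, 0.5), got {self.error_rate}"
            )
        if self.contamination is not None:
            idx, frac = self.contamination
            if not 0 <= idx < self.true_S.k:
                raise ValueError(
                    f"contaminated sample index {idx} out of range for k={self.true_S.k}"
                )
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"contamination fraction must be in [0, 1], got {frac}")

    @property
    def k(self) -> int:
        return self.true_S.k

    @classmethod
    def create(
        cls,
        true_S: SourceVector | Sequence[int] | str,
        L: int,
        maf_window: tuple[float, float],
        lam: float | Sequence[float],
        error_rate: float = 0.01,
        contamination: tuple[int, float] | None = None,
        seed: int = 0,
    ) -> "SimConfig":
        if isinstance(true_S, str):
            true_S = SourceVector.from_string(true_S)
        elif not isinstance(true_S, SourceVector):
            true_S = SourceVector(tuple(true_S))
        if np.isscalar(lam):
            lambdas = (float(lam),) * true_S.k
        else:
            lambdas = tuple(float(x) for x in lam)
        return cls(
            true_S=true_S,
            L=int(L),
            maf_window=(float(maf_window[0]), float(maf_window[1])),
            lambda_per_sample=lambdas,
            error_rate=float(error_rate),
            contamination=contamination,
            seed=int(seed),
        )


@dataclass(frozen=True)
class SimTruth:
    """Ground truth behind a simulated dataset.

    ``source_genotypes`` has shape ``(n_sources, L)`` holding B-allele
    counts in {0, 1, 2}; ``freq_B`` the per-site B-allele frequencies the
    genotypes were drawn from. When contamination is active,
    ``contaminated_site_mask`` flags the affected sites of
    ``contaminant_sample`` and ``contaminant_genotypes`` gives the foreign
    genotype at every site (only masked entries are ever used).
    """

    true_S: SourceVector
    freq_B: np.ndarray
    source_genotypes: np.ndarray
    contaminated_site_mask: np.ndarray
    contaminant_sample: int | None
    contaminant_genotypes: np.ndarray | None
    seed: int

    @property
    def L(self) -> int:
        return self.freq_B.shape[0]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def simulate_site_frequencies(
    L: int, maf_window: tuple[float, float], seed: int | np.random.Generator
) -> np.ndarray:
    """Draw per-site B-allele frequencies with MAF in ``(lo, hi]``.

    The MAF is uniform on the half-open window; with probability 0.5 the
    B allele is made the major allele (frequency ``1 - maf``), so B is
    minor or major with equal chance.
    """
    lo, hi = float(maf_window[0]), float(maf_window[1])
    if not 0.0 <= lo < hi <= 0.5:
        raise ValueError(
            f"maf_window must satisfy 0 <= lo < hi <= 0.5, got {maf_window}"
        )
    rng = np.random.default_rng(seed)
    # 1 - U maps [0, 1) draws onto the half-open interval (lo, hi].
    maf = lo + (hi - lo) * (1.0 - rng.random(L))
    flip = rng.random(L) < 0.5
    return np.where(flip, 1.0 - maf, maf)


def simulate_source_genotypes(
    true_S: SourceVector, freqs: np.ndarray, seed: int | np.random.Generator
) -> SimTruth:
    """Draw one HWE genotype per distinct source per site.

    A genotype is the number of B alleles, so a Binomial(2, f) draw;
    samples sharing a source label share the genotype at every site.
    """
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    genotypes = rng.binomial(2, freqs[None, :].repeat(true_S.n_sources, axis=0))
    seed_val = seed if isinstance(seed, int) else -1
    return SimTruth(
        true_S=true_S,
        freq_B=freqs,
        source_genotypes=genotypes,
        contaminated_site_mask=np.zeros(freqs.shape[0], dtype=bool),
        contaminant_sample=None,
        contaminant_genotypes=None,
        seed=seed_val,
    )


def inject_contamination(
    truth: SimTruth, sample_index: int, p: float, seed: int | np.random.Generator
) -> SimTruth:
    """Contaminate one sample at ``round(p * L)`` sites.

    The affected sites are chosen uniformly without replacement; at each,
    the sample's reads will derive from an independent HWE genotype drawn
    at that site's frequency. Rounding is half-up, so ``p=0.5, L=1000``
    contaminates exactly 500 sites.
    """
    if not 0 <= sample_index < truth.true_S.k:
        raise ValueError(
            f"sample index {sample_index} out of range for k={truth.true_S.k}"
        )
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"contamination fraction must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    n_cont = _round_half_up(p * truth.L)
    mask = np.zeros(truth.L, dtype=bool)
    if n_cont:
        mask[rng.choice(truth.L, size=n_cont, replace=False)] = True
    contaminant = rng.binomial(2, truth.freq_B)
    return replace(
        truth,
        contaminated_site_mask=mask,
        contaminant_sample=sample_index,
        contaminant_genotypes=contaminant,
    )


def simulate_allele_depths(
    truth: SimTruth,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> ReplicateDataset:
    """Draw allelic depths from the truth under the observation model.

    Per sample and site the depth is Poisson with the sample's mean; the
    B-read count is binomial in the depth with success probability ``e``,
    ``0.5`` or ``1 - e`` given the governing genotype (the source's, or
    the contaminant's at masked sites of the contaminated sample).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    L, k = truth.L, config.k
    p_b_by_g = np.array([config.error_rate, 0.5, 1.0 - config.error_rate])
    depths = np.empty((L, k, 2), dtype=np.int64)
    for d in range(k):
        g = truth.source_genotypes[truth.true_S.labels[d] - 1].copy()
        if truth.contaminant_sample == d and truth.contaminant_genotypes is not None:
            g[truth.contaminated_site_mask] = truth.contaminant_genotypes[
                truth.contaminated_site_mask
            ]
        total = rng.poisson(config.lambda_per_sample[d], size=L)
        n_b = rng.binomial(total, p_b_by_g[g])
        depths[:, d, 0] = total - n_b
        depths[:, d, 1] = n_b
    pos = 1 + np.arange(L, dtype=np.int64) * _SITE_SPACING
    return ReplicateDataset(
        sample_ids=[f"rep{d + 1}" for d in range(k)],
        chrom=[_SIM_CHROM] * L,
        pos=pos,
        freq_B=truth.freq_B,
        depths=depths,
        error_rate=config.error_rate,
    )


def simulate_dataset(config: SimConfig) -> tuple[ReplicateDataset, SimTruth]:
    """Run the full generative pipeline for one configuration.

    Deterministic in ``config.seed``: frequencies, genotypes,
    contamination and reads each consume an independent child stream.
    """
    ss = np.random.SeedSequence(config.seed)
    s_freq, s_geno, s_cont, s_reads = ss.spawn(4)
    freqs = simulate_site_frequencies(
        config.L, config.maf_window, np.random.default_rng(s_freq)
    )
    truth = simulate_source_genotypes(
        config.true_S, freqs, np.random.default_rng(s_geno)
    )
    truth = replace(truth, seed=config.seed)
    if config.contamination is not None:
        idx, frac = config.contamination
        truth = inject_contamination(
            truth, idx, frac, np.random.default_rng(s_cont)
        )
    data = simulate_allele_depths(truth, config, np.random.default_rng(s_reads))
    return data, truth


# ---------------------------------------------------------------------------
# Experiment drivers
# ---------------------------------------------------------------------------

DEFAULT_DEPTH_GRID = (1.0, 2.0, 3.0, 6.0, 15.0)
DEFAULT_MAF_WINDOWS = (
    (0.0, 0.1),
    (0.1, 0.2),
    (0.2, 0.3),
    (0.3, 0.4),
    (0.4, 0.5),
)
DEFAULT_L_GRID = (50, 100, 250, 500, 1000, 2000, 5000)
DEFAULT_CONTAMINATION_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_UNEQUAL_DEPTH_GRID = (1.0, 2.0, 4.0, 6.0, 12.0)


def _score_one(config: SimConfig) -> dict:
    data, _ = simulate_dataset(config)
    result = joint_posterior(data, threshold=0.99)
    top_sv, top_p = result.top()
    return {
        "true_S": str(config.true_S),
        "L": config.L,
        "maf_min": config.maf_window[0],
        "maf_max": config.maf_window[1],
        "error_rate": config.error_rate,
        "seed": config.seed,
        "posterior_true": result.posterior_of(config.true_S),
        "top_S": str(top_sv),
        "top_posterior": top_p,
        "correct": str(top_sv) == str(config.true_S),
    }


def _cell_rows(base: SimConfig, reps: int, ss: np.random.SeedSequence) -> list[dict]:
    rows = []
    for rep, child in enumerate(ss.spawn(reps)):
        seed = int(child.generate_state(1)[0])
        row = _score_one(replace(base, seed=seed))
        row["rep"] = rep
        rows.append(row)
    return rows


def run_accuracy_grid(
    k: int = 3,
    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID,
    maf_windows: Sequence[tuple[float, float]] = DEFAULT_MAF_WINDOWS,
    L: int = 1000,
    reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Depth-by-MAF accuracy grid: one source-vector class per block-size
    profile, full factorial over mean depth and MAF window, ``reps``
    simulate-infer cycles per cell. Returns one tidy row per cycle."""
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for sv in source_vector_classes(k):
        for lam in depth_grid:
            for window in maf_windows:
                base = SimConfig.create(sv, L, window, lam)
                for row in _cell_rows(base, reps, ss.spawn(1)[0]):
                    row.update({"experiment": "accuracy_grid", "lam": float(lam)})
                    rows.append(row)
    return pd.DataFrame(rows)


def run_l_sweep(
    true_vectors: Sequence[SourceVector | str] = ("1,2,1", "1,2,3"),
    L_grid: Sequence[int] = DEFAULT_L_GRID,
    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID,
    maf_window: tuple[float, float] = (0.2, 0.3),
    reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Sweep the number of analyzed sites ``L`` at a fixed MAF window."""
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for sv in true_vectors:
        for lam in depth_grid:
            for L in L_grid:
                base = SimConfig.create(sv, L, maf_window, lam)
                for row in _cell_rows(base, reps, ss.spawn(1)[0]):
                    row.update({"experiment": "l_sweep", "lam": float(lam)})
                    rows.append(row)
    return pd.DataFrame(rows)


def run_sensitivity(
    contamination_grid: Sequence[float] = DEFAULT_CONTAMINATION_GRID,
    depth_grid: Sequence[float] = DEFAULT_DEPTH_GRID,
    L: int = 1000,
    maf_window: tuple[float, float] = (0.4, 0.5),
    reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Contamination sensitivity: true partition (1,1), sample 2
    contaminated at each fraction-by-depth combination."""
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for frac in contamination_grid:
        for lam in depth_grid:
            base = SimConfig.create(
                "1,1", L, maf_window, lam, contamination=(1, float(frac))
            )
            for row in _cell_rows(base, reps, ss.spawn(1)[0]):
                row.update(
                    {
                        "experiment": "sensitivity",
                        "lam": float(lam),
                        "contamination": float(frac),
                    }
                )
                rows.append(row)
    return pd.DataFrame(rows)


def run_unequal_depths(
    true_vectors: Sequence[SourceVector | str] = ("1,1", "1,2", "1,2,1"),
    varied_depth_grid: Sequence[float] = DEFAULT_UNEQUAL_DEPTH_GRID,
    base_depth: float = 1.0,
    maf_windows: Sequence[tuple[float, float]] = DEFAULT_MAF_WINDOWS,
    L: int = 1000,
    reps: int = 25,
    seed: int = 0,
) -> pd.DataFrame:
    """Unequal-depth study: all samples at ``base_depth`` except the last,
    whose mean depth runs over ``varied_depth_grid``."""
    ss = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for sv in true_vectors:
        sv = sv if isinstance(sv, SourceVector) else SourceVector.from_string(str(sv))
        for lam in varied_depth_grid:
            lambdas = (base_depth,) * (sv.k - 1) + (float(lam),)
            for window in maf_windows:
                base = SimConfig.create(sv, L, window, lambdas)
                for row in _cell_rows(base, reps, ss.spawn(1)[0]):
                    row.update(
                        {
                            "experiment": "unequal_depths",
                            "lam": float(lam),
                            "base_depth": float(base_depth),
                        }
                    )
                    rows.append(row)
    return pd.DataFrame(rows)


def summarize_cells(df: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the true-partition posterior per cell.

    Groups by every design column present in the tidy table (everything
    except the per-replicate outcome columns)."""
    outcome = {"posterior_true", "top_S", "top_posterior", "correct", "rep", "seed"}
    keys = [c for c in df.columns if c not in outcome]
    agg = (
        df.groupby(keys, dropna=False)["posterior_true"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n="count",
        )
        .reset_index()
    )
    recovery = (
        df.groupby(keys, dropna=False)["correct"].mean().reset_index(name="recovery")
    )
    return agg.merge(recovery, on=keys)
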