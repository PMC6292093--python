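"""Bayesian identity model over partitions of putative sequencing replicates.

Given ``k`` sequence runs that are all recorded as coming from one
individual, every hypothesis about which runs truly share a genotypic
source is a labeled set partition of the ``k`` samples, encoded here as a
:class:`SourceVector` (a canonical restricted-growth string whose first
element is 1; equal labels mean "same underlying genotype").

The model scores each partition directly from per-site allelic read
counts, with no genotype calling:

* per-sample genotype likelihoods are binomial in the B-allele read count
  with success probability ``e``, ``0.5`` or ``1 - e`` for the three
  diploid genotypes (``e`` is a symmetric sequencing error rate);
* genotypes are marginalized under Hardy–Weinberg priors built from
  user-supplied population B-allele frequencies, with samples in the same
  partition block constrained to share one genotype;
* sites are treated as independent, so per-site log marginals add, and
  the posterior over partitions is normalized by log-sum-exp.

All probability arithmetic is carried out in log space: with ~1000 sites
the per-partition likelihoods underflow double precision in linear space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "MAX_K",
    "BELL_NUMBERS",
    "GenotypeCode",
    "SourceVector",
    "SiteAlleleDepth",
    "SiteRecord",
    "ReplicateDataset",
    "PosteriorResult",
    "canonicalize",
    "enumerate_source_vectors",
    "source_vector_classes",
    "genotype_log_likelihood",
    "hwe_genotype_log_prior",
    "genotype_vector_log_prior",
    "site_log_likelihood",
    "joint_posterior",
    "posterior_odds",
    "non_replicate_rate",
]

#: Hard cap on the number of putative replicates analyzed jointly. The
#: number of partitions grows as the Bell numbers (4140 already at k = 8),
#: so joint analysis beyond this is impractical and is refused outright.
MAX_K = 8

#: Bell numbers B(0)..B(8); ``BELL_NUMBERS[k]`` counts the source vectors
#: of length ``k``.
BELL_NUMBERS = (1, 1, 2, 5, 15, 52, 203, 877, 4140)

#: Tie tolerance for the posterior maximum: two partitions closer than
#: this are considered indistinguishable and suppress the call.
_TIE_ATOL = 1e-12


class GenotypeCode(IntEnum):
    """Diploid biallelic genotype as a count of B alleles."""

    AA = 0
    AB = 1
    BB = 2


# ---------------------------------------------------------------------------
# Source vectors (canonical labeled partitions)
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class SourceVector:
    """A labeled partition of ``k`` samples into genotypic sources.

    ``labels[d]`` is the source index of sample ``d``; equal labels mean
    the samples are hypothesized to share an identical genotype. The
    encoding is the canonical restricted-growth string: the first label is
    1 and each label is at most one greater than the maximum of its
    predecessors, which makes the representation of each set partition
    unique.

    Examples
    --------
    >>> SourceVector((1, 2, 1)).groups()
    {1: (0, 2), 2: (1,)}
    >>> str(SourceVector.from_string("1,2,1"))
    '1,2,1'
    """

    labels: tuple[int, ...]

    def __post_init__(self) -> None:
        labels = tuple(int(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 1:
            raise ValueError("a source vector needs at least one element")
        hi = 0
        for d, lab in enumerate(labels):
            if lab < 1 or lab > hi + 1:
                raise ValueError(
                    f"labels {labels} are not a canonical restricted-growth "
                    f"string (element {d} is {lab}, allowed 1..{hi + 1})"
                )
            hi = max(hi, lab)

    @property
    def k(self) -> int:
        """Number of samples described."""
        return len(self.labels)

    @property
    def n_sources(self) -> int:
        """Number of distinct genotypic sources (partition blocks)."""
        return max(self.labels)

    def groups(self) -> dict[int, tuple[int, ...]]:
        """Map each source label to the ordered sample indices carrying it."""
        out: dict[int, list[int]] = {}
        for d, lab in enumerate(self.labels):
            out.setdefault(lab, []).append(d)
        return {lab: tuple(ds) for lab, ds in out.items()}

    @classmethod
    def identical(cls, k: int) -> "SourceVector":
        """The all-samples-identical ("no errors") partition of size ``k``."""
        return cls((1,) * k)

    @classmethod
    def from_string(cls, text: str) -> "SourceVector":
        """Parse a comma-joined label string such as ``"1,2,1"``."""
        try:
            labels = tuple(int(tok) for tok in text.split(","))
        except ValueError as err:
            raise ValueError(f"cannot parse source vector {text!r}") from err
        return cls(labels)

    def __str__(self) -> str:
        return ",".join(str(lab) for lab in self.labels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.labels)

    def __len__(self) -> int:
        return len(self.labels)


def canonicalize(labels: Sequence[int]) -> SourceVector:
    """Relabel an arbitrary grouping into canonical restricted-growth form.

    Labels are rewritten in order of first appearance, so any two
    sequences inducing the same partition map to the same
    :class:`SourceVector`.
    """
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out.append(mapping[lab])
    return SourceVector(tuple(out))


def enumerate_source_vectors(k: int) -> tuple[SourceVector, ...]:
    """Enumerate every source vector of length ``k``.

    Returns all canonical restricted-growth strings in lexicographic
    order; the count is the ``k``-th Bell number.

    Raises
    ------
    ValueError
        If ``k`` is outside ``[1, MAX_K]``.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise ValueError(f"k must be an integer, got {k!r}")
    if k < 1 or k > MAX_K:
        raise ValueError(
            f"k must be between 1 and {MAX_K} (joint analysis of more than "
            f"{MAX_K} putative replicates is not supported); got k={k}"
        )
    out: list[SourceVector] = []
    labels = [1] * k

    def extend(d: int, hi: int) -> None:
        if d == k:
            out.append(SourceVector(tuple(labels)))
            return
        for lab in range(1, hi + 2):
            labels[d] = lab
            extend(d + 1, max(hi, lab))

    extend(1, 1)  # first label is pinned to 1
    return tuple(out)


def source_vector_classes(k: int) -> tuple[SourceVector, ...]:
    """One representative source vector per block-size profile.

    Partitions whose blocks have the same multiset of sizes behave
    identically under sample relabeling (e.g. ``1,1,2``, ``1,2,1`` and
    ``1,2,2`` for ``k=3``), so simulation studies only need one of each.
    The representative is the lexicographically first member of the class.
    """
    seen: dict[tuple[int, ...], SourceVector] = {}
    for sv in enumerate_source_vectors(k):
        profile = tuple(sorted((len(g) for g in sv.groups().values()), reverse=True))
        seen.setdefault(profile, sv)
    return tuple(seen.values())


# ---------------------------------------------------------------------------
# Per-site data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteAlleleDepth:
    """Read counts supporting alleles A and B for one sample at one site."""

    n_A: int
    n_B: int

    def __post_init__(self) -> None:
        if self.n_A < 0 or self.n_B < 0:
            raise ValueError(
                f"allele depths must be non-negative, got ({self.n_A}, {self.n_B})"
            )

    @property
    def total(self) -> int:
        return self.n_A + self.n_B


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site: position, population B-allele frequency and the
    per-replicate allelic depths."""

    chrom: str
    pos: int
    freq_B: float
    depths: tuple[SiteAlleleDepth, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.freq_B <= 1.0:
            raise ValueError(f"freq_B must be in [0, 1], got {self.freq_B}")
        if len(self.depths) < 1:
            raise ValueError("a site needs at least one sample depth")

    @property
    def k(self) -> int:
        return len(self.depths)


class ReplicateDataset:
    """Allelic-depth data for ``k`` putative replicates at ``L`` sites.

    Internally array-backed: ``depths`` has shape ``(L, k, 2)`` with the
    A-allele count in channel 0 and the B-allele count in channel 1.

    Parameters
    ----------
    sample_ids
        ``k`` sample labels.
    chrom, pos
        Per-site chromosome names and 1-based positions (length ``L``).
    freq_B
        Per-site population frequency of allele B, in ``[0, 1]``.
    depths
        Integer array of shape ``(L, k, 2)``.
    error_rate
        Symmetric per-read sequencing error rate, strictly inside
        ``(0, 0.5)``. ``e = 0`` is rejected: a single discordant read
        would then zero out otherwise-plausible genotypes.
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
        freq_B: Sequence[float],
        depths: np.ndarray,
        error_rate: float = 0.01,
    ) -> None:
        self.sample_ids = tuple(str(s) for s in sample_ids)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.freq_B = np.asarray(freq_B, dtype=float)
        self.depths = np.asarray(depths, dtype=np.int64)
        if not 0.0 < error_rate < 0.5:
            raise ValueError(
                f"error_rate must lie strictly in (0, 0.5), got {error_rate}"
            )
        self.error_rate = float(error_rate)

        L = self.depths.shape[0] if self.depths.ndim == 3 else -1
        k = len(self.sample_ids)
        if self.depths.ndim != 3 or self.depths.shape[1:] != (k, 2):
            raise ValueError(
                f"depths must have shape (L, {k}, 2), got {self.depths.shape}"
            )
        if L < 1:
            raise ValueError("dataset needs at least one site")
        if not (len(self.chrom) == len(self.pos) == len(self.freq_B) == L):
            raise ValueError("chrom, pos, freq_B and depths disagree on L")
        if (self.depths < 0).any():
            raise ValueError("allele depths must be non-negative")
        if ((self.freq_B < 0) | (self.freq_B > 1)).any():
            raise ValueError("freq_B values must lie in [0, 1]")

    @property
    def k(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        return self.depths.shape[0]

    @classmethod
    def from_sites(
        cls,
        sample_ids: Sequence[str],
        sites: Sequence[SiteRecord],
        error_rate: float = 0.01,
    ) -> "ReplicateDataset":
        """Build a dataset from :class:`SiteRecord` values."""
        k = len(sample_ids)
        if any(site.k != k for site in sites):
            raise ValueError("all sites must carry one depth per sample")
        depths = np.array(
            [[(d.n_A, d.n_B) for d in site.depths] for site in sites],
            dtype=np.int64,
        ).reshape(len(sites), k, 2)
        return cls(
            sample_ids=sample_ids,
            chrom=[s.chrom for s in sites],
            pos=[s.pos for s in sites],
            freq_B=[s.freq_B for s in sites],
            depths=depths,
            error_rate=error_rate,
        )

    def site(self, i: int) -> SiteRecord:
        """Materialize site ``i`` as a :class:`SiteRecord`."""
        return SiteRecord(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            freq_B=float(self.freq_B[i]),
            depths=tuple(
                SiteAlleleDepth(int(a), int(b)) for a, b in self.depths[i]
            ),
        )

    def sites(self) -> Iterator[SiteRecord]:
        for i in range(self.L):
            yield self.site(i)

    def reorder_samples(self, order: Sequence[int]) -> "ReplicateDataset":
        """Return a copy with samples re-ordered: new sample ``j`` is the
        old sample ``order[j]``."""
        order = list(order)
        if sorted(order) != list(range(self.k)):
            raise ValueError(f"order must be a permutation of 0..{self.k - 1}")
        return ReplicateDataset(
            sample_ids=[self.sample_ids[i] for i in order],
            chrom=self.chrom,
            pos=self.pos,
            freq_B=self.freq_B,
            depths=self.depths[:, order, :],
            error_rate=self.error_rate,
        )


# ---------------------------------------------------------------------------
# Likelihoods and priors
# ---------------------------------------------------------------------------


def _validate_error_rate(e: float) -> None:
    if not 0.0 < e < 0.5:
        raise ValueError(f"error rate must lie strictly in (0, 0.5), got {e}")


def _b_read_probs(e: float) -> np.ndarray:
    """Per-read probability of observing allele B for each genotype."""
    return np.array([e, 0.5, 1.0 - e])


def genotype_log_likelihood(
    x: SiteAlleleDepth | tuple[int, int],
    g: GenotypeCode | int,
    e: float,
) -> float:
    """Log-likelihood of genotype ``g`` given allele depths ``x``.

    Binomial in the B-allele count: ``n_B ~ Binomial(n_A + n_B, p_B)``
    with ``p_B = e`` for AA, ``0.5`` for AB and ``1 - e`` for BB. The
    binomial coefficient is included; it cancels in the posterior over
    partitions but keeps individual values interpretable as probabilities.
    A ``(0, 0)`` depth contributes log(1) = 0.
    """
    if isinstance(x, SiteAlleleDepth):
        n_a, n_b = x.n_A, x.n_B
    else:
        n_a, n_b = int(x[0]), int(x[1])
    if n_a < 0 or n_b < 0:
        raise ValueError(f"allele depths must be non-negative, got ({n_a}, {n_b})")
    _validate_error_rate(e)
    g = GenotypeCode(g)
    n = n_a + n_b
    if n == 0:
        return 0.0
    p_b = _b_read_probs(e)[int(g)]
    log_coef = (
        math.lgamma(n + 1) - math.lgamma(n_a + 1) - math.lgamma(n_b + 1)
    )
    return log_coef + n_a * math.log1p(-p_b) + n_b * math.log(p_b)


def hwe_genotype_log_prior(freq_B: float) -> np.ndarray:
    """Log Hardy–Weinberg genotype probabilities ``((1-f)^2, 2f(1-f), f^2)``.

    ``freq_B`` must lie strictly inside ``(0, 1)``; monomorphic sites carry
    no information and are excluded upstream rather than clamped here.
    """
    f = float(freq_B)
    if not 0.0 < f < 1.0:
        raise ValueError(
            f"freq_B must lie strictly in (0, 1); got {f} — monomorphic "
            "sites must be excluded before scoring"
        )
    return np.array(
        [
            2.0 * math.log1p(-f),
            math.log(2.0) + math.log(f) + math.log1p(-f),
            2.0 * math.log(f),
        ]
    )


def genotype_vector_log_prior(
    G: Sequence[GenotypeCode | int],
    S: SourceVector,
    freq_B: float,
) -> float:
    """Log prior probability of a genotype vector given a partition.

    Samples sharing a source label must share a genotype (otherwise the
    prior is zero, returned as ``-inf``); each distinct source contributes
    one independent Hardy–Weinberg draw.
    """
    if len(G) != S.k:
        raise ValueError(
            f"genotype vector has length {len(G)} but source vector k={S.k}"
        )
    log_hwe = hwe_genotype_log_prior(freq_B)
    total = 0.0
    for members in S.groups().values():
        genotypes = {int(GenotypeCode(G[d])) for d in members}
        if len(genotypes) > 1:
            return float("-inf")
        total += log_hwe[genotypes.pop()]
    return total


# ---------------------------------------------------------------------------
# Site and joint likelihoods
# ---------------------------------------------------------------------------


def _genotype_loglik_cube(depths: np.ndarray, e: float) -> np.ndarray:
    """Per-sample genotype log-likelihoods; shape ``(L, k, 3)``.

    Vectorized binomial log-pmf of the B-allele count under each of the
    three genotypes' B-read probabilities.
    """
    n_a = depths[..., 0].astype(float)
    n_b = depths[..., 1].astype(float)
    n = n_a + n_b
    log_coef = gammaln(n + 1) - gammaln(n_a + 1) - gammaln(n_b + 1)
    cube = np.empty(depths.shape[:2] + (3,))
    for gi, p_b in enumerate(_b_read_probs(e)):
        cube[..., gi] = log_coef + n_a * math.log1p(-p_b) + n_b * math.log(p_b)
    return cube


def _hwe_logprior_matrix(freq_B: np.ndarray) -> np.ndarray:
    """Per-site HWE genotype log-priors; shape ``(L, 3)``."""
    f = np.asarray(freq_B, dtype=float)
    if ((f <= 0.0) | (f >= 1.0)).any():
        bad = f[(f <= 0.0) | (f >= 1.0)][0]
        raise ValueError(
            f"freq_B must lie strictly in (0, 1) for all scored sites; "
            f"found {bad}"
        )
    return np.stack(
        [
            2.0 * np.log1p(-f),
            math.log(2.0) + np.log(f) + np.log1p(-f),
            2.0 * np.log(f),
        ],
        axis=-1,
    )


def _partition_site_logliks(
    cube: np.ndarray, log_prior: np.ndarray, S: SourceVector
) -> np.ndarray:
    """Per-site log P(X | S); shape ``(L,)``.

    Factorizes over partition blocks: each block marginalizes one shared
    genotype over its members' likelihood product, so the cost per site is
    ``k * 3`` rather than ``3 ** k``.
    """
    total = np.zeros(cube.shape[0])
    for members in S.groups().values():
        block = cube[:, list(members), :].sum(axis=1) + log_prior
        total += logsumexp(block, axis=1)
    return total


def site_log_likelihood(site: SiteRecord, S: SourceVector, e: float) -> float:
    """Log marginal likelihood of one site's depths under partition ``S``.

    Equal (up to floating-point) to the explicit sum over all ``3**k``
    genotype vectors of the likelihood product times the genotype-vector
    prior; computed by block factorization.
    """
    if site.k != S.k:
        raise ValueError(
            f"site carries {site.k} depths but source vector k={S.k}"
        )
    _validate_error_rate(e)
    depths = np.array(
        [[(d.n_A, d.n_B) for d in site.depths]], dtype=np.int64
    )
    cube = _genotype_loglik_cube(depths, e)
    log_prior = _hwe_logprior_matrix(np.array([site.freq_B]))
    return float(_partition_site_logliks(cube, log_prior, S)[0])


@dataclass(eq=False)
class PosteriorResult:
    """Posterior over all source vectors for one individual.

    Attributes
    ----------
    vectors
        All source vectors of length ``k`` in enumeration order.
    log_likelihoods
        Per-vector log P(X | S) summed over sites.
    log_posterior
        Normalized per-vector log posterior.
    posterior
        Per-vector posterior probabilities (sum to 1).
    called
        The maximum-posterior vector if it reached ``threshold`` and is
        untied, else ``None``.
    threshold
        The call threshold used.
    """

    vectors: tuple[SourceVector, ...]
    log_likelihoods: np.ndarray
    log_posterior: np.ndarray
    posterior: np.ndarray
    called: SourceVector | None
    threshold: float

    _index: dict[SourceVector, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {sv: i for i, sv in enumerate(self.vectors)}

    @property
    def k(self) -> int:
        return self.vectors[0].k

    def index_of(self, S: SourceVector) -> int:
        try:
            return self._index[S]
        except KeyError:
            raise ValueError(
                f"source vector {S} is not among the {len(self.vectors)} "
                f"vectors of this result (k={self.k})"
            ) from None

    def posterior_of(self, S: SourceVector) -> float:
        return float(self.posterior[self.index_of(S)])

    def log_likelihood_of(self, S: SourceVector) -> float:
        return float(self.log_likelihoods[self.index_of(S)])

    def top(self) -> tuple[SourceVector, float]:
        i = int(np.argmax(self.posterior))
        return self.vectors[i], float(self.posterior[i])

    def as_mapping(self) -> dict[str, float]:
        """Posterior as ``{"1,2,1": p, ...}`` in enumeration order."""
        return {str(sv): float(p) for sv, p in zip(self.vectors, self.posterior)}


def joint_posterior(
    data: ReplicateDataset,
    prior: Mapping[SourceVector, float] | Sequence[float] | None = None,
    threshold: float = 0.99,
) -> PosteriorResult:
    """Posterior probability of every source vector given all sites.

    Per-vector log-likelihoods are sums of per-site block-factorized log
    marginals; the posterior is normalized with a max-shifted log-sum-exp.
    ``prior`` defaults to uniform over partitions; if supplied it must be
    a proper distribution over ``enumerate_source_vectors(k)``. A call is
    made only when the maximum posterior reaches ``threshold`` and is not
    tied (within 1e-12) with another vector.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must lie in (0, 1], got {threshold}")
    vectors = enumerate_source_vectors(data.k)
    log_prior_s = _coerce_prior(prior, vectors)

    cube = _genotype_loglik_cube(data.depths, data.error_rate)
    site_log_prior = _hwe_logprior_matrix(data.freq_B)
    log_liks = np.array(
        [
            _partition_site_logliks(cube, site_log_prior, sv).sum()
            for sv in vectors
        ]
    )

    unnorm = log_liks + log_prior_s
    log_post = unnorm - logsumexp(unnorm)
    posterior = np.exp(log_post)

    i_max = int(np.argmax(posterior))
    p_max = posterior[i_max]
    tied = np.sum(posterior >= p_max - _TIE_ATOL) > 1
    called = vectors[i_max] if (p_max >= threshold and not tied) else None

    return PosteriorResult(
        vectors=vectors,
        log_likelihoods=log_liks,
        log_posterior=log_post,
        posterior=posterior,
        called=called,
        threshold=threshold,
    )


def _coerce_prior(
    prior: Mapping[SourceVector, float] | Sequence[float] | None,
    vectors: tuple[SourceVector, ...],
) -> np.ndarray:
    """Validate a prior over partitions and return its log, aligned with
    ``vectors``. ``None`` means uniform."""
    n = len(vectors)
    if prior is None:
        return np.full(n, -math.log(n))
    if isinstance(prior, Mapping):
        missing = [sv for sv in vectors if sv not in prior]
        if missing:
            raise ValueError(
                f"prior is missing {len(missing)} source vectors, e.g. {missing[0]}"
            )
        values = np.array([float(prior[sv]) for sv in vectors])
    else:
        values = np.asarray(prior, dtype=float)
        if values.shape != (n,):
            raise ValueError(
                f"prior must have one entry per source vector ({n}), got "
                f"shape {values.shape}"
            )
    if (values < 0).any():
        raise ValueError("prior probabilities must be non-negative")
    if abs(values.sum() - 1.0) > 1e-9:
        raise ValueError(
            f"prior must sum to 1 within 1e-9, got {values.sum()!r}"
        )
    with np.errstate(divide="ignore"):
        return np.log(values)


def posterior_odds(
    result: PosteriorResult, S1: SourceVector, S2: SourceVector
) -> float:
    """Posterior odds of ``S1`` against ``S2``.

    Computed in log space, so it stays finite even when one posterior
    underflows to 0 in linear space. Under the uniform prior this equals
    the likelihood ratio.
    """
    i, j = result.index_of(S1), result.index_of(S2)
    return float(np.exp(result.log_posterior[i] - result.log_posterior[j]))


def non_replicate_rate(result: PosteriorResult) -> float:
    """One minus the posterior probability of the all-identical partition."""
    return 1.0 - result.posterior_of(SourceVector.identical(result.k))
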