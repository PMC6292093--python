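"""VCF input, allele-frequency estimation and analysis-site sampling.

Reads per-sample allelic depths (the ``AD`` FORMAT field) from biallelic
SNP records, estimates population B-allele (ALT) frequencies either from
a reference panel within the same file or from a user-supplied table, and
samples the sites actually scored by the model: MAF window, minimum
inter-site distance and a read-presence requirement per replicate.

Allele "B" is bound to the VCF ALT allele throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .partition_model import ReplicateDataset

logger = logging.getLogger(__name__)

__all__ = [
    "SiteCatalog",
    "SamplingConfig",
    "read_allele_depths",
    "estimate_allele_frequencies",
    "load_frequency_table",
    "apply_frequency_table",
    "sample_sites",
    "write_dataset_tsv",
    "read_dataset_tsv",
]

_SNP_ALLELES = frozenset("ACGT")


@dataclass
class SiteCatalog:
    """All usable biallelic SNP records of a VCF for a set of samples.

    ``depths`` has shape ``(n_sites, n_samples, 2)`` with REF (= allele A)
    counts in channel 0 and ALT (= allele B) counts in channel 1.
    ``freq_B`` is NaN until frequencies are estimated or supplied.
    """

    sample_ids: tuple[str, ...]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    depths: np.ndarray
    freq_B: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if self.freq_B is None:
            self.freq_B = np.full(len(self.pos), np.nan)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise ValueError(
                f"unknown sample {sample_id!r}; available: "
                f"{', '.join(self.sample_ids)}"
            ) from None


@dataclass(frozen=True)
class SamplingConfig:
    """Filters and budget for analysis-site sampling.

    The MAF window is half-open, ``(maf_min, maf_max]``; ``min_distance``
    is in base pairs within a chromosome; ``require_read_each`` demands at
    least one read in every replicate sample at the site.
    """

    L: int = 1000
    maf_min: float = 0.4
    maf_max: float = 0.5
    min_distance: int = 20_000
    seed: int = 0
    require_read_each: bool = True

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError(f"L must be at least 1, got {self.L}")
        if not 0.0 <= self.maf_min < self.maf_max <= 0.5:
            raise ValueError(
                f"need 0 <= maf_min < maf_max <= 0.5, got "
                f"({self.maf_min}, {self.maf_max}]"
            )
        if self.min_distance < 0:
            raise ValueError(f"min_distance must be >= 0, got {self.min_distance}")


def read_allele_depths(
    vcf_source: str | Path, sample_ids: list[str] | None = None
) -> SiteCatalog:
    """Load allelic depths for biallelic SNP records from a VCF.

    Multiallelic records, indels and records whose positions do not
    strictly increase within a chromosome are skipped (counted in
    ``n_skipped``); missing AD entries become ``(0, 0)``.

    Raises a format error if the file declares no per-sample ``AD`` field,
    and an argument error naming the available samples if ``sample_ids``
    contains an unknown name.
    """
    from cyvcf2 import VCF

    path = str(vcf_source)
    probe = VCF(path)
    available = list(probe.samples)
    try:
        probe.get_header_type("AD")
    except KeyError:
        raise ValueError(
            f"VCF {path} has no AD FORMAT field; per-sample allelic depths "
            "are required"
        ) from None
    finally:
        probe.close()

    if sample_ids is not None:
        unknown = [s for s in sample_ids if s not in available]
        if unknown:
            raise ValueError(
                f"unknown sample(s) {', '.join(unknown)}; available: "
                f"{', '.join(available)}"
            )
        vcf = VCF(path, samples=list(sample_ids))
    else:
        vcf = VCF(path)
    kept_samples = tuple(vcf.samples)

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    depth_rows: list[np.ndarray] = []
    n_skipped = 0
    last_seen: dict[str, int] = {}

    for record in vcf:
        if (
            len(record.ALT) != 1
            or record.REF not in _SNP_ALLELES
            or record.ALT[0] not in _SNP_ALLELES
        ):
            n_skipped += 1
            continue
        if last_seen.get(record.CHROM, 0) >= record.POS:
            n_skipped += 1  # unsorted or duplicate position
            continue
        ad = record.format("AD")
        if ad is None:
            n_skipped += 1
            continue
        ad = np.asarray(ad, dtype=np.int64)[:, :2]
        ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
        last_seen[record.CHROM] = record.POS
        chroms.append(record.CHROM)
        positions.append(record.POS)
        refs.append(record.REF)
        alts.append(record.ALT[0])
        depth_rows.append(ad)
    vcf.close()

    if n_skipped:
        logger.info("skipped %d unusable VCF records", n_skipped)
    if not depth_rows:
        logger.warning("no usable biallelic SNP records found in %s", path)
        depths = np.zeros((0, len(kept_samples), 2), dtype=np.int64)
    else:
        depths = np.stack(depth_rows)

    return SiteCatalog(
        sample_ids=kept_samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        depths=depths,
        n_skipped=n_skipped,
    )


def estimate_allele_frequencies(
    catalog: SiteCatalog, panel_sample_ids: list[str]
) -> np.ndarray:
    """Pooled-read estimate of the per-site B-allele frequency.

    ``freq_B = sum(ALT reads) / sum(all reads)`` over the panel samples;
    sites where the panel has zero reads are returned as NaN (undefined)
    and are excluded later by site sampling.
    """
    if not panel_sample_ids:
        raise ValueError("panel must contain at least one sample")
    idx = [catalog.sample_index(s) for s in panel_sample_ids]
    pool = catalog.depths[:, idx, :].sum(axis=1)
    total = pool.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(total > 0, pool[:, 1] / total, np.nan)
    return freqs


def load_frequency_table(path: str | Path) -> pd.DataFrame:
    """Read a ``chrom  pos  freq_B`` TSV (header required, 1-based pos)."""
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "freq_B"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(
            f"frequency table {path} lacks column(s): {', '.join(sorted(missing))}"
        )
    return table


def apply_frequency_table(catalog: SiteCatalog, path: str | Path) -> np.ndarray:
    """Per-site frequencies looked up from a user table; NaN where absent."""
    table = load_frequency_table(path)
    lookup = {
        (str(c), int(p)): float(f)
        for c, p, f in zip(table["chrom"], table["pos"], table["freq_B"])
    }
    return np.array(
        [
            lookup.get((str(c), int(p)), np.nan)
            for c, p in zip(catalog.chrom, catalog.pos)
        ]
    )


def sample_sites(
    catalog: SiteCatalog,
    config: SamplingConfig,
    replicate_ids: list[str],
    error_rate: float = 0.01,
) -> ReplicateDataset:
    """Sample up to ``L`` analysis sites and pack the replicates' depths.

    Candidates must have a defined, polymorphic frequency with MAF in
    ``(maf_min, maf_max]`` and, when ``require_read_each`` is set, at
    least one read in every replicate. Candidates are visited in seeded
    random order and accepted greedily if at least ``min_distance`` bp
    from every already-accepted site on the same chromosome. Accepted
    sites are returned in genomic order. Fewer than ``L`` qualifying
    candidates yields a warning, zero an error suggesting a wider MAF
    window.
    """
    rep_idx = [catalog.sample_index(s) for s in replicate_ids]
    freqs = catalog.freq_B
    maf = np.minimum(freqs, 1.0 - freqs)
    eligible = (
        ~np.isnan(freqs)
        & (freqs > 0.0)
        & (freqs < 1.0)
        & (maf > config.maf_min)
        & (maf <= config.maf_max)
    )
    if config.require_read_each:
        read_counts = catalog.depths[:, rep_idx, :].sum(axis=2)
        eligible &= (read_counts >= 1).all(axis=1)
    candidates = np.flatnonzero(eligible)
    logger.info(
        "%d of %d sites pass MAF/read filters", len(candidates), catalog.n_sites
    )
    if len(candidates) == 0:
        raise ValueError(
            "no sites satisfy the filters; widen the MAF window "
            f"({config.maf_min}, {config.maf_max}] or relax the read requirement"
        )

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(candidates))
    accepted: list[int] = []
    taken_by_chrom: dict[str, list[int]] = {}
    for j in order:
        i = int(candidates[j])
        c, p = str(catalog.chrom[i]), int(catalog.pos[i])
        taken = taken_by_chrom.setdefault(c, [])
        if any(abs(p - q) < config.min_distance for q in taken):
            continue
        taken.append(p)
        accepted.append(i)
        if len(accepted) == config.L:
            break
    if len(accepted) < config.L:
        logger.warning(
            "only %d of the requested L=%d sites qualify", len(accepted), config.L
        )

    accepted_arr = np.array(sorted(accepted), dtype=np.int64)
    return ReplicateDataset(
        sample_ids=replicate_ids,
        chrom=catalog.chrom[accepted_arr],
        pos=catalog.pos[accepted_arr],
        freq_B=freqs[accepted_arr],
        depths=catalog.depths[accepted_arr][:, rep_idx, :],
        error_rate=error_rate,
    )


# ---------------------------------------------------------------------------
# Interchange TSV (the plain-text fixture format)
# ---------------------------------------------------------------------------


def write_dataset_tsv(data: ReplicateDataset, path: str | Path) -> None:
    """Write a dataset as TSV: chrom, pos, freq_B, then nA/nB per sample.

    Frequencies are written with ``repr`` so the round trip is exact.
    """
    with open(path, "w") as fh:
        cols = ["chrom", "pos", "freq_B"]
        for sid in data.sample_ids:
            cols += [f"{sid}_nA", f"{sid}_nB"]
        fh.write("\t".join(cols) + "\n")
        for i in range(data.L):
            row = [str(data.chrom[i]), str(int(data.pos[i])), repr(float(data.freq_B[i]))]
            for d in range(data.k):
                row += [str(int(data.depths[i, d, 0])), str(int(data.depths[i, d, 1]))]
            fh.write("\t".join(row) + "\n")


def read_dataset_tsv(path: str | Path, error_rate: float = 0.01) -> ReplicateDataset:
    """Read a dataset written by :func:`write_dataset_tsv`."""
    table = pd.read_csv(
        path, sep="\t", dtype={"chrom": str}, float_precision="round_trip"
    )
    fixed = {"chrom", "pos", "freq_B"}
    missing = fixed - set(table.columns)
    if missing:
        raise ValueError(
            f"dataset TSV {path} lacks column(s): {', '.join(sorted(missing))}"
        )
    sample_ids = []
    for col in table.columns:
        if col.endswith("_nA"):
            sid = col[:-3]
            if f"{sid}_nB" not in table.columns:
                raise ValueError(f"column {sid}_nB missing from {path}")
            sample_ids.append(sid)
    if not sample_ids:
        raise ValueError(f"dataset TSV {path} carries no nA/nB column pairs")
    depths = np.stack(
        [
            np.stack(
                [table[f"{sid}_nA"].to_numpy(), table[f"{sid}_nB"].to_numpy()],
                axis=1,
            )
            for sid in sample_ids
        ],
        axis=1,
    ).astype(np.int64)
    return ReplicateDataset(
        sample_ids=sample_ids,
        chrom=table["chrom"].to_numpy(dtype=object),
        pos=table["pos"].to_numpy(dtype=np.int64),
        freq_B=table["freq_B"].to_numpy(dtype=float),
        depths=depths,
        error_rate=error_rate,
    )
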