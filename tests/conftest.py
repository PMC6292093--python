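import numpy as np
import pytest

from replicheck import ReplicateDataset


def write_vcf(path, samples, records, with_ad=True):
    """Write a minimal VCF. ``records`` rows are
    (chrom, pos, ref, alt, per_sample_ad) with per_sample_ad a list of
    (nA, nB) tuples or None for missing."""
    fmt_ad = (
        '##FORMAT=<ID=AD,Number=R,Type=Integer,'
        'Description="Allelic depths for the ref and alt alleles">\n'
        if with_ad
        else ""
    )
    contigs = sorted({chrom for chrom, *_ in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in contigs:
            fh.write(f"##contig=<ID={chrom},length=100000000>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(fmt_ad)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, ads in records:
            cells = []
            for ad in ads:
                if with_ad:
                    ad_str = "." if ad is None else f"{ad[0]},{ad[1]}"
                    cells.append(f"./.:{ad_str}")
                else:
                    cells.append("./.")
            fmt = "GT:AD" if with_ad else "GT"
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    counter = {"n": 0}

    def factory(samples, records, with_ad=True):
        counter["n"] += 1
        return str(
            write_vcf(tmp_path / f"fixture{counter['n']}.vcf", samples, records, with_ad)
        )

    return factory


@pytest.fixture
def rng():
    return np.random.default_rng(20260903)


def random_dataset(rng, k=3, L=20, max_depth=4, error_rate=0.01):
    """Small random dataset with well-behaved frequencies."""
    depths = rng.integers(0, max_depth + 1, size=(L, k, 2))
    freqs = rng.uniform(0.05, 0.95, size=L)
    return ReplicateDataset(
        sample_ids=[f"s{i}" for i in range(k)],
        chrom=["chr1"] * L,
        pos=(1 + np.arange(L) * 30000),
        freq_B=freqs,
        depths=depths,
        error_rate=error_rate,
    )


@pytest.fixture
def small_dataset(rng):
    return random_dataset(rng)
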