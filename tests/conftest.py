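import pytest

from panhap.synthetic import PangenomeSpec, simulate_pangenome


@pytest.fixture(scope="session")
def pangenome():
    """Three cultivars on a 12-Mb chromosome.

    cv0/cv1 share two planted identical blocks (2-5 Mb and 8-10 Mb) on a
    near-identical background; cv2 shares nothing; cv1 carries an
    introgression-like divergent segment; all three have N runs.
    """
    spec = PangenomeSpec(
        n_cultivars=3,
        chrom_len=12_000_000,
        planted_blocks=[((0, 1), 2_000_001, 5_000_000),
                        ((0, 1), 8_000_001, 10_000_000)],
        introgressions=[(1, 10_500_001, 11_500_000, 0.007)],
        n_runs=[(0, 2_500_000, 8_000), (1, 9_000_000, 6_000),
                (0, 6_500_000, 9_000), (2, 4_000_000, 7_000)],
        blast_flanks=(0, 2000),
        seed=11,
    )
    return simulate_pangenome(spec)


@pytest.fixture(scope="session")
def pair_records(pangenome):
    return pangenome.alignments[("cv0", "cv1")]


@pytest.fixture(scope="session")
def ref_projections(pangenome):
    return [p for p in pangenome.projections if p.assembly == "cv0"]
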