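import numpy as np
import pytest

from paracnv import CountMatrix, GeneInterval, SampleMeta


def make_record(read_id, chrom, start, seq="A" * 36, mapq=40, quals=None):
    from paracnv import AlignmentRecord

    quals = tuple(quals) if quals is not None else (40,) * len(seq)
    return AlignmentRecord(
        read_id=read_id, chrom=chrom, start=start, read_length=len(seq),
        mapq=mapq, sequence=seq, base_qualities=quals,
    )


@pytest.fixture
def toy_filter_matrix():
    """Ten genes exercising both filter rules and the equality boundary.

    With 4 individuals of 1e6 mapped reads each:
      g0 len 1000, counts [8,8,8,8]     -> median/100bp = 0.8 < 1 -> removed
      g1 len 1000, counts [10,10,10,10] -> exactly 1.0 -> retained
      g2 len 500,  counts [5,9,0,7]     -> zero individual -> removed
      g3 len 200,  counts [4,4,4,4]     -> 2.0 -> retained
      g4 len 4000, counts [40,41,39,40] -> ~1.0 -> retained
      g5 len 4000, counts [39,39,40,40] -> 0.9875 < 1 -> removed
      g6 len 100,  counts [1,1,1,1]     -> 1.0 -> retained
      g7 len 1000, counts [0,0,0,0]     -> both rules -> removed
      g8 len 300,  counts [2,3,9,4]     -> median 3.5*100/300 ~ 1.17 -> retained
      g9 len 2000, counts [30,10,25,9]  -> median 17.5*100/2000 = 0.875 -> removed
    """
    lengths = [1000, 1000, 500, 200, 4000, 4000, 100, 1000, 300, 2000]
    counts = np.array([
        [8, 8, 8, 8],
        [10, 10, 10, 10],
        [5, 9, 0, 7],
        [4, 4, 4, 4],
        [40, 41, 39, 40],
        [39, 39, 40, 40],
        [1, 1, 1, 1],
        [0, 0, 0, 0],
        [2, 3, 9, 4],
        [30, 10, 25, 9],
    ])
    genes = []
    pos = 0
    for i, ln in enumerate(lengths):
        genes.append(GeneInterval(f"g{i}", "chr1", pos, pos + ln))
        pos += 2 * ln
    samples = [
        SampleMeta(f"s{j}", "freshwater" if j < 2 else "marine", 1_000_000)
        for j in range(4)
    ]
    matrix = CountMatrix(genes=genes, samples=samples, counts=counts)
    expected_survivors = ["g1", "g3", "g4", "g6", "g8"]
    return matrix, expected_survivors


@pytest.fixture(scope="session")
def signal_run():
    """One shared paper-shaped detection run (2,000 genes, 24 true GCNVs)."""
    import paracnv as pc

    cfg = pc.parallel_selection_scenario(n_genes=2000, seed=3)
    matrices, truth = pc.simulate_count_matrices(cfg)
    result = pc.run_detection(matrices, "freshwater", "marine")
    return cfg, matrices, truth, result
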