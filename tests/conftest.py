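"""Shared fixtures: a hand-enumerated cascade scenario and small helpers.

The cascade fixture plants 30 per-sample peak calls across three genes so
that each filtering stage removes a known peak: support-1 calls die at the
merge, intergenic and wrong-strand peaks at the host-gene step, an
unenriched peak at the input filter, a low-count peak at the amplitude
filter, and a peak in a lowly expressed gene at the expression filter.
"""

import numpy as np
import pytest

from eprint_tools.core import (CountTable, GeneExpressionTable, GeneModel,
                               GenomicInterval, Peak, SampleInfo)


def mkpeak(chrom, start, end, strand, pid, host=None, support=1):
    return Peak(GenomicInterval(chrom, start, end, strand), pid,
                support=support, host_gene=host)


def build_cascade_genes():
    g1 = GeneModel("G1", "chr1", "+", [(1000, 1800), (2200, 3000)],
                   utr5=[(1000, 1100)], utr3=[(2900, 3000)])
    g2 = GeneModel("G2", "chr1", "-", [(5000, 7000)],
                   utr5=[(6800, 7000)], utr3=[(5000, 5150)])
    g3 = GeneModel("G3", "chr1", "+", [(9000, 9500)])
    return [g1, g2, g3]


@pytest.fixture(scope="session")
def cascade_genes():
    return build_cascade_genes()


# scenario name -> (interval strand, per-sample call intervals, eprint sum,
#                   input sum, expected fate)
CASCADE_SCENARIOS = {
    "M1": ("+", {0: (1195, 1255), 1: (1200, 1260), 2: (1205, 1265),
                 3: (1198, 1258)}, 400, 10, "survives"),
    "M2": ("+", {0: (2295, 2345), 1: (2305, 2355)}, 100, 2, "survives"),
    "M3": ("+", {0: (1500, 1550)}, 0, 0, "merge"),
    "M4": ("+", {0: (4000, 4050), 1: (4000, 4050), 2: (4000, 4050)},
           300, 3, "intragenic"),
    "M5": ("+", {0: (5500, 5550), 1: (5500, 5550), 2: (5500, 5550),
                 3: (5500, 5550)}, 300, 3, "intragenic"),
    "M6": ("-", {0: (5600, 5660), 1: (5600, 5660), 2: (5600, 5660),
                 3: (5600, 5660)}, 60, 60, "enrichment"),
    "M7": ("-", {1: (5800, 5840), 2: (5800, 5840)}, 45, 1, "peak_count"),
    "M8": ("+", {0: (9100, 9140), 1: (9100, 9140)}, 200, 5, "gene_count"),
    "M9": ("-", {0: (6000, 6060), 1: (6000, 6060), 3: (6000, 6060)},
           120, 10, "survives"),
    "M10": ("+", {2: (1600, 1660), 3: (1600, 1660)}, 80, 4, "survives"),
    "M11": ("-", {0: (4200, 4240), 1: (4200, 4240), 2: (4200, 4240)},
            120, 2, "intragenic"),
}


def build_cascade_fixture():
    """(per_sample_calls, merged_count_builder, gene_expr, expectations)."""
    samples = ([SampleInfo(f"ep{r}", "eprint", "ctrl" if r < 2 else "kd")
                for r in range(4)]
               + [SampleInfo(f"in{r}", "input", "ctrl" if r < 2 else "kd")
                  for r in range(4)])
    per_sample = [[] for _ in range(4)]
    for name, (strand, calls, *_rest) in CASCADE_SCENARIOS.items():
        for si, (s, e) in calls.items():
            per_sample[si].append(
                mkpeak("chr1", s, e, strand, f"{name}_s{si}"))

    def counts_for(merged_peaks):
        """Distribute each scenario's eprint/input sums over the samples of
        the merged peak that envelops it."""
        mat = np.zeros((len(merged_peaks), 8), dtype=np.int64)
        for i, mp in enumerate(merged_peaks):
            for name, (strand, calls, ep_sum, in_sum, _) in \
                    CASCADE_SCENARIOS.items():
                s, e = next(iter(calls.values()))
                probe = GenomicInterval("chr1", s, e, strand)
                if mp.interval.overlaps(probe):
                    mat[i, :4] += np.array([ep_sum // 4] * 3
                                           + [ep_sum - 3 * (ep_sum // 4)])
                    mat[i, 4:] += np.array([in_sum // 4] * 3
                                           + [in_sum - 3 * (in_sum // 4)])
        return CountTable([p.peak_id for p in merged_peaks], samples, mat)

    gene_expr = GeneExpressionTable(
        ["G1", "G2", "G3"], samples[4:],
        np.array([[100] * 4, [50] * 4, [10] * 4]))
    expected_survivor_scenarios = {n for n, v in CASCADE_SCENARIOS.items()
                                   if v[4] == "survives"}
    return per_sample, counts_for, gene_expr, expected_survivor_scenarios


@pytest.fixture(scope="session")
def cascade_fixture():
    return build_cascade_fixture()


def scenario_of_merged(mp):
    """Which hand-built scenario a merged peak came from."""
    for name, (strand, calls, *_rest) in CASCADE_SCENARIOS.items():
        s, e = next(iter(calls.values()))
        if mp.interval.overlaps(GenomicInterval("chr1", s, e, strand)):
            return name
    return None
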