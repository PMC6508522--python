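"""Printed benchmark values from the two-accession dark-period study.

These small tables are inputs for validation: the differential-
expression benchmark lists each candidate DEG's raw read counts in the
SH and YK accessions together with the printed log2(YK/SH) fold (one
decimal) or absence label, plus the qRT-PCR verdict; the sugar table
holds the per-experiment maltose and glucose mean relative
concentrations that feed the starch-degradation proxy.
"""

from __future__ import annotations

import pandas as pd

# gene, SH reads, YK reads, printed fold (1 dp) or absence label, qRT verdict
DEG_BENCHMARK_ROWS = [
    ("Thhalv10021382", 4, 87, 4.4, 12.5),
    ("Thhalv10000662", 46, 429, 3.2, 4.4),
    ("Thhalv10015083", 34265, 2494, -3.8, -5661.5),
    ("Thhalv10011087", 1445, 327, -2.1, "n.s."),
    ("XLOC_024729", 237, 25, -3.2, -2.0),
    ("Thhalv10015718", 0, 48, "Absent in SH", "Not detected in SH"),
    ("Thhalv10029390", 0, 83, "Absent in SH", "Not detected in SH"),
    ("Thhalv10021522", 1, 244, 7.9, 144.9),
    ("Thhalv10014718", 1, 86, 6.4, 11.8),
    ("Thhalv10002969", 61, 0, "Absent in YK", -58.3),
    ("Thhalv10009345", 58, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10014264", 53, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10000285", 179, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10022943", 148, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10023491", 47, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10018393", 70, 1, -6.1, 1.7),
    ("XLOC_005768", 0, 99, "Absent in SH", "Not detected in SH"),
    ("XLOC_017575", 50, 0, "Absent in YK", "Not detected in YK"),
    ("XLOC_003055", 55, 0, "Absent in YK", "Not detected in YK"),
    ("XLOC_024727", 53, 0, "Absent in YK", "Not detected in YK"),
    ("XLOC_003052", 318, 1, -8.3, -257.7),
    ("XLOC_008740", 135, 3, -5.5, "Not detected in YK"),
    ("XLOC_020731", 76, 0, "Absent in YK", "Not detected in YK"),
    ("XLOC_017573", 246, 0, "Absent in YK", "Not detected in YK"),
    ("XLOC_015175", 75, 0, "Absent in YK", "Not detected in YK"),
    ("Thhalv10022994", 0, 46, "Absent in SH", "Not tested"),
    ("Thhalv10022932", 74, 1, -6.2, "Not tested"),
    ("Thhalv10014933", 295, 32, -3.2, "Not tested"),
    ("Thhalv10019398", 6, 217, 5.2, "Not tested"),
    ("Thhalv10029246", 0, 47, "Absent in SH", "Not tested"),
    ("XLOC_004723", 187, 16, -3.5, "Not tested"),
]


def deg_benchmark() -> pd.DataFrame:
    return pd.DataFrame(
        DEG_BENCHMARK_ROWS,
        columns=["gene", "count_sh", "count_yk", "printed_fold", "qrt_fold"],
    )


# metabolite, experiment, genotype, mean relative concentration
SUGAR_MEAN_ROWS = [
    ("Maltose", 1, "SH", 1119.8),
    ("Maltose", 1, "YK", 678.6),
    ("Maltose", 2, "SH", 1081.4),
    ("Maltose", 2, "YK", 846.2),
    ("Glucose", 1, "SH", 41843.5),
    ("Glucose", 1, "YK", 28552.0),
    ("Glucose", 2, "SH", 16547.4),
    ("Glucose", 2, "YK", 6251.4),
]


def sugar_means() -> pd.DataFrame:
    return pd.DataFrame(
        SUGAR_MEAN_ROWS, columns=["metabolite", "experiment", "genotype", "mean"]
    )
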