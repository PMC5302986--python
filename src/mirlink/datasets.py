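"""Bundled reference data: the published tamoxifen-resistance miRNA screen.

The screen profiled three tamoxifen-resistant MCF-7 sublines (TamR1, TamR4,
TamR8) against their parental tamoxifen-sensitive line (MCF-7/S0.5) with
LNA-based qPCR panels, and reported the log2 fold changes of the 22 miRNAs
whose altered expression was significant (adjusted p < 0.05) in every
resistant line.  The matrix is a worked example for the sign-consistency
signature and the fold-change candidate filter.
"""

from __future__ import annotations

import io

import pandas as pd

from .differential_expression import DEResult

__all__ = [
    "resistant_line_screen",
    "resistant_line_de_results",
    "RESISTANT_LINES",
    "REFERENCE_LINE",
]

RESISTANT_LINES = ("TamR1", "TamR4", "TamR8")
REFERENCE_LINE = "MCF-7/S0.5"

# log2 fold changes (resistant vs. parental), one column per resistant line;
# every entry passed adjusted p < 0.05 in the published screen
_SCREEN_TSV = """\
mirna\tTamR1\tTamR4\tTamR8
miR-101*\t-1.02\t-3.05\t-1.37
miR-1201\t-0.94\t-1.36\t-1.27
miR-1248\t-1.68\t-1.61\t-1.01
miR-652\t-1.99\t-1.17\t-1.64
miR-95\t-1.82\t-2.45\t-1.19
miR-135b\t-1.89\t-2.16\t-2.33
miR-196a\t-1.54\t-0.71\t-1.65
miR-135a\t-2.84\t-6.16\t-4.74
miR-130b\t0.75\t0.94\t0.89
miR-130b*\t1.06\t1.55\t0.88
miR-152\t1.29\t1.4\t1.49
miR-181b\t0.89\t1.14\t0.95
miR-203\t2.2\t1.34\t1.12
miR-210\t0.7\t1.18\t1.49
miR-22*\t0.97\t0.88\t0.82
miR-339-5p\t1\t1.26\t0.8
miR-516a-5p\t3.47\t2.87\t2.46
miR-517c\t2.06\t1.66\t1.06
miR-519a\t2.23\t1.69\t1.2
miR-519e\t1.98\t1.15\t0.97
miR-551b\t2.09\t5.79\t3.51
miR-582-5p\t2.43\t0.86\t1.93
"""


def resistant_line_screen() -> pd.DataFrame:
    """The 22 x 3 log2 fold-change matrix of the published screen.

    Rows are miRNAs, columns the three resistant sublines; values are log2
    fold changes versus the parental line.
    """
    return pd.read_csv(io.StringIO(_SCREEN_TSV), sep="\t", index_col=0)


def resistant_line_de_results() -> list[DEResult]:
    """The screen wrapped as one differential-expression result per subline.

    The published table reports only that every entry passed the adjusted
    p < 0.05 cutoff; the wrapped results encode that significance call (see
    :meth:`DEResult.from_reported`), making the matrix directly usable by
    the sign-consistency signature filter.
    """
    lfc = resistant_line_screen()
    return [
        DEResult.from_reported(lfc[line], contrast=(line, REFERENCE_LINE))
        for line in RESISTANT_LINES
    ]
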