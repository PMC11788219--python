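"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own metric implementations: kappa is
computed by explicit enumeration of the N paired labels behind a 2x2 table.
"""

import math


def kappa_by_enumeration(tp: int, fp: int, fn: int, tn: int) -> float:
    """Cohen's kappa from an explicit list of paired labels."""
    ref = [1] * tp + [1] * fn + [0] * fp + [0] * tn
    test = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    n = len(ref)
    if n == 0:
        raise ValueError("empty table")
    p_o = sum(1 for r, t in zip(ref, test) if r == t) / n
    p_ref = sum(ref) / n
    p_test = sum(test) / n
    p_e = p_ref * p_test + (1 - p_ref) * (1 - p_test)
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else math.nan
    return (p_o - p_e) / (1.0 - p_e)
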