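"""Exact dyadic-rational accumulation for area-weighted field statistics.

IEEE-754 doubles are dyadic rationals, so sums and dot products of floats
have exact representations with power-of-two denominators.  Computing the
numerator and denominator of a normalized metric exactly and rounding once
at the end makes ratios such as AWSS/parent-WSS cancel a common scale
factor of the field *exactly*: if every field value w_i is replaced by
c*w_i without rounding (true for any c when the w_i are float32-quantized
and c is a small integer, e.g. 10), the returned double is bit-identical.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable

import numpy as np

__all__ = ["exact_sum", "exact_dot"]


def _accumulate(pairs: Iterable[tuple[int, int]]) -> Fraction:
    # value = acc_num / 2**acc_exp; denominators of float ratios are 2**k
    acc_num = 0
    acc_exp = 0
    for num, den in pairs:
        e = den.bit_length() - 1  # den == 2**e exactly for finite floats
        if e > acc_exp:
            acc_num <<= (e - acc_exp)
            acc_exp = e
            acc_num += num
        else:
            acc_num += num << (acc_exp - e)
    return Fraction(acc_num, 1 << acc_exp)


def exact_sum(values: np.ndarray) -> Fraction:
    """Exact sum of an array of finite floats as a Fraction."""
    return _accumulate(float(v).as_integer_ratio()
                       for v in np.asarray(values, dtype=float).tolist())


def exact_dot(a: np.ndarray, b: np.ndarray) -> Fraction:
    """Exact dot product of two arrays of finite floats as a Fraction."""
    av = np.asarray(a, dtype=float).tolist()
    bv = np.asarray(b, dtype=float).tolist()
    if len(av) != len(bv):
        raise ValueError("length mismatch")

    def pairs():
        for x, y in zip(av, bv):
            n1, d1 = x.as_integer_ratio()
            n2, d2 = y.as_integer_ratio()
            yield n1 * n2, d1 * d2

    return _accumulate(pairs())
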