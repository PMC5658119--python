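"""Independent brute-force oracles used to cross-check the vectorized
implementations.  These deliberately share no code with the package: every
touched base is enumerated read by read, position by position."""

import numpy as np


def wrap(p: int, length: int) -> int:
    return (p - 1) % length + 1


def brute_five_prime(records, length: int, circular: bool):
    plus = np.zeros(length)
    minus = np.zeros(length)
    for rec in records:
        if rec.strand.value == "plus":
            p = wrap(rec.start, length) if circular else rec.start
            plus[p - 1] += 1
        else:
            p = rec.start + rec.read_length - 1
            p = wrap(p, length) if circular else p
            minus[p - 1] += 1
    return plus, minus


def brute_cleavage(plus, minus, length: int, circular: bool):
    cp = np.zeros(length)
    cm = np.zeros(length)
    for i in range(length):
        p = i + 1
        if plus[i]:
            q = wrap(p - 1, length) if circular else p - 1
            if 1 <= q <= length:
                cp[q - 1] += plus[i]
        if minus[i]:
            q = wrap(p + 1, length) if circular else p + 1
            if 1 <= q <= length:
                cm[q - 1] += minus[i]
    return cp, cm


def brute_occupancy(records, length: int, circular: bool, extsize: int):
    plus = np.zeros(length)
    minus = np.zeros(length)
    for rec in records:
        if rec.strand.value == "plus":
            e5 = wrap(rec.start, length) if circular else rec.start
            span = range(e5, e5 + extsize)
            target = plus
        else:
            e5 = rec.start + rec.read_length - 1
            e5 = wrap(e5, length) if circular else e5
            span = range(e5 - extsize + 1, e5 + 1)
            target = minus
        for p in span:
            if circular:
                target[wrap(p, length) - 1] += 1
            elif 1 <= p <= length:
                target[p - 1] += 1
    return plus, minus


def brute_frames(cuts, target, tol, length: int):
    """All ordered circular cut pairs with strictly-between length within
    target +/- tol, by direct position counting."""
    out = []
    for a in sorted(set(cuts)):
        for b in sorted(set(cuts)):
            if a == b:
                continue
            d = (b - a) % length
            strict = d - 1 if d > 1 else 0
            if abs(strict - target) <= tol:
                out.append((a, b, strict))
    return sorted(out)
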