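"""First-principles reference implementation used only as a test oracle.

Everything here is written with plain Python loops and sorting —
deliberately sharing no code with the package — so agreement between
the two routes checks the pipeline against the definitions directly.
"""

import math


def median(values):
    s = sorted(values)
    n = len(s)
    m = n // 2
    return s[m] if n % 2 else (s[m - 1] + s[m]) / 2.0


def quantile(values, q):
    """Linear interpolation of order statistics at h = q*(n-1)+1."""
    s = sorted(values)
    n = len(s)
    h = q * (n - 1)
    lo = math.floor(h)
    g = h - lo
    if lo + 1 < n:
        return s[lo] + g * (s[lo + 1] - s[lo])
    return s[lo]


def mad(values):
    m = median(values)
    return median([abs(x - m) for x in values])


def core_interval(values, mult=0.9, dispersion="mad"):
    q1, q3 = quantile(values, 0.25), quantile(values, 0.75)
    d = mad(values) if dispersion == "mad" else q3 - q1
    return (q1 - mult * d, q3 + mult * d)


def score_gene(row, labels, mult=0.9, dispersion="mad"):
    """Full per-gene computation straight from the definitions."""
    n = len(row)
    cls = {c: [row[i] for i in range(n) if labels[i] == c] for c in (0, 1)}
    iv = {c: core_interval(cls[c], mult, dispersion) for c in (0, 1)}
    ov_lo = max(iv[0][0], iv[1][0])
    ov_hi = min(iv[0][1], iv[1][1])
    ov_empty = ov_lo > ov_hi
    ov_len = 0.0 if ov_empty else ov_hi - ov_lo
    tot = (min(iv[0][0], iv[1][0]), max(iv[0][1], iv[1][1]))
    tot_len = tot[1] - tot[0]

    N = {i for i in range(n) if iv[labels[i]][0] <= row[i] <= iv[labels[i]][1]}
    O = set() if ov_empty else {i for i in N if ov_lo <= row[i] <= ov_hi}
    Oprime = N - O
    counts = tuple(sum(1 for i in O if labels[i] == c) for c in (0, 1))

    if len(N) == 0 or tot_len == 0.0:
        rpos = 1.0
    elif len(O) == 0:
        rpos = 0.0
    else:
        phi0 = counts[0] / len(O)
        phi1 = counts[1] / len(O)
        rpos = 4.0 * (ov_len / tot_len) * (len(O) / len(N)) * phi0 * phi1

    mask = [1 if i in Oprime else 0 for i in range(n)]
    frac = [
        sum(mask[i] for i in range(n) if labels[i] == c) / len(cls[c])
        for c in (0, 1)
    ]
    rdc = 0 if frac[0] >= frac[1] else 1
    return {
        "intervals": iv,
        "overlap_len": ov_len,
        "total": tot,
        "N": N,
        "O": O,
        "Oprime": Oprime,
        "counts": counts,
        "rpos": rpos,
        "mask": mask,
        "rdc": rdc,
    }
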