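"""Independent brute-force reference implementations used only by tests.

Deliberately written in plain Python loops, with no code shared with the
package, so agreement with the package is a genuine cross-check.
"""

import math

AMINO = "ACDEFGHIKLMNPQRSTVWY"


def brute_composition(seq):
    out = []
    for a in AMINO:
        n = 0
        for c in seq:
            if c == a:
                n += 1
        out.append(n / len(seq) * 100.0)
    return out


def brute_ctd(seq, groups):
    """21-value C/T/D block by literal counting.

    ``groups`` is a 3-tuple of letter strings.
    """
    L = len(seq)
    which = {}
    for gi, g in enumerate(groups):
        for letter in g:
            which[letter] = gi
    codes = [which[c] for c in seq]

    comp = []
    for gi in range(3):
        n = 0
        for c in codes:
            if c == gi:
                n += 1
        comp.append(n / L * 100.0)

    trans = []
    for gi, gj in ((0, 1), (0, 2), (1, 2)):
        n = 0
        for k in range(L - 1):
            a, b = codes[k], codes[k + 1]
            if (a == gi and b == gj) or (a == gj and b == gi):
                n += 1
        trans.append(n / (L - 1) * 100.0)

    dist = []
    for gi in range(3):
        positions = []
        for k, c in enumerate(codes):
            if c == gi:
                positions.append(k + 1)  # 1-based
        n = len(positions)
        if n == 0:
            dist.extend([0.0] * 5)
            continue
        for j in range(5):
            if j == 0:
                p = 1
            else:
                p = (n * j) // 4
                if p < 1:
                    p = 1
            dist.append(positions[p - 1] / L * 100.0)
    return comp + trans + dist


def brute_188(seq, grouping_strings):
    """Full fingerprint: composition then one CTD block per property.

    ``grouping_strings`` is a list of eight 3-tuples of letter strings.
    """
    out = brute_composition(seq)
    for groups in grouping_strings:
        out.extend(brute_ctd(seq, groups))
    return out


def brute_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    if sx == 0 or sy == 0:
        return 0.0
    return cov / (sx * sy)


def brute_minmax_columns(rows):
    n = len(rows)
    p = len(rows[0])
    out = [[0.0] * p for _ in range(n)]
    for j in range(p):
        col = [rows[i][j] for i in range(n)]
        lo, hi = min(col), max(col)
        for i in range(n):
            out[i][j] = 0.5 if hi == lo else (rows[i][j] - lo) / (hi - lo)
    return out


def brute_mrmd_order(rows, labels, wr=1.0, wd=1.0):
    """(order, scores) by literal re-derivation of the MRMD ranking."""
    n = len(rows)
    p = len(rows[0])
    rel = [abs(brute_pearson([rows[i][j] for i in range(n)], labels))
           for j in range(p)]
    scaled = brute_minmax_columns(rows)
    dist = []
    for j in range(p):
        total = 0.0
        for k in range(p):
            if k == j:
                continue
            d2 = sum((scaled[i][j] - scaled[i][k]) ** 2 for i in range(n))
            total += math.sqrt(d2) / math.sqrt(n)
        dist.append(total / (p - 1))
    score = [wr * r + wd * d for r, d in zip(rel, dist)]
    order = sorted(range(p), key=lambda j: (-score[j], j))
    return order, score


def brute_kmer_counts(s, k, alphabet="HEC"):
    """word -> percentage of windows, for words actually present."""
    n_windows = len(s) - k + 1
    counts = {}
    for i in range(n_windows):
        w = s[i: i + k]
        counts[w] = counts.get(w, 0) + 1
    return {w: c / n_windows * 100.0 for w, c in counts.items()}
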