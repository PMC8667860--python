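"""Independent brute-force reference implementations.

Everything here is written with explicit Python loops straight from the
defining formulas, deliberately sharing no code with the package, so that
agreement is a meaningful check on the vectorised implementations.
"""

from __future__ import annotations

import math

AA = "ARNDCQEGHILKMFPSTVWY"


def aac_oracle(scores) -> list[float]:
    L = len(scores)
    return [sum(scores[i][j] for i in range(L)) / L for j in range(20)]


def dpc_oracle(scores) -> list[float]:
    L = len(scores)
    out = []
    for i in range(20):
        for j in range(20):
            s = 0.0
            for k in range(L - 1):
                s += scores[k][i] * scores[k + 1][j]
            out.append(s / (L - 1))
    return out


def composition_unscaled_oracle(scores, residues) -> list[list[float]]:
    L = len(scores)
    comp = [[0.0] * 20 for _ in range(20)]
    for pos, res in enumerate(residues):
        if res in AA:
            a = AA.index(res)
            for j in range(20):
                comp[a][j] += scores[pos][j]
    return [[v / L for v in row] for row in comp]


def minmax_scale_oracle(flat) -> list[float]:
    lo, hi = min(flat), max(flat)
    if hi == lo:
        return [0.0] * len(flat)
    return [2.0 * (v - lo) / (hi - lo) - 1.0 for v in flat]


def composition_oracle(scores, residues) -> list[float]:
    comp = composition_unscaled_oracle(scores, residues)
    return minmax_scale_oracle([v for row in comp for v in row])


def reduce_oracle(scores, groups) -> list[list[float]]:
    out = []
    for row in scores:
        out.append(
            [sum(row[AA.index(a)] for a in g) / len(g) for g in groups]
        )
    return out


def rpssm_oracle(scores, groups, difference=True) -> list[float]:
    r = reduce_oracle(scores, groups)
    L = len(r)
    out = []
    for s in range(10):
        mean = sum(r[i][s] for i in range(L)) / L
        out.append(sum((r[i][s] - mean) ** 2 for i in range(L)) / L)
    for s in range(10):
        for t in range(10):
            acc = 0.0
            for i in range(L - 1):
                pair = r[i][s] - r[i + 1][t] if difference else r[i][s] + r[i + 1][t]
                acc += pair**2 / 2.0
            out.append(acc / (L - 1))
    return out


# ---------------------------------------------------------------------------
# MRMD


def pearson_oracle(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[k] - mx) * (y[k] - my) for k in range(n))
    den = math.sqrt(
        sum((x[k] - mx) ** 2 for k in range(n)) * sum((y[k] - my) ** 2 for k in range(n))
    )
    return 0.0 if den == 0 else num / den


def distances_oracle(x, y) -> tuple[float, float, float]:
    ed = math.sqrt(sum((a - b) ** 2 for a, b in zip(x, y)))
    dot = sum(a * b for a, b in zip(x, y))
    nx = sum(a * a for a in x)
    ny = sum(b * b for b in y)
    if nx == 0 or ny == 0:
        return ed, 0.0, 0.0
    return ed, dot / math.sqrt(nx * ny), dot / (nx + ny - dot)


def mrmd_oracle(values, labels, normalize_ed=True, weight=0.5):
    """Full O(M^2 N) ranking: returns (maxmr, ed, cos, tc, maxmd, score, rank)."""
    n = len(values)
    m = len(values[0])
    cols = [[values[i][j] for i in range(n)] for j in range(m)]
    maxmr = [abs(pearson_oracle(c, list(labels))) for c in cols]
    ed = [0.0] * m
    cos = [0.0] * m
    tc = [0.0] * m
    if m > 1:
        for i in range(m):
            for k in range(m):
                if k == i:
                    continue
                e, c, t = distances_oracle(cols[i], cols[k])
                ed[i] += e
                cos[i] += c
                tc[i] += t
            ed[i] /= m - 1
            cos[i] /= m - 1
            tc[i] /= m - 1
    ed_used = list(ed)
    if normalize_ed and m > 1:
        lo, hi = min(ed), max(ed)
        ed_used = [0.0] * m if hi == lo else [(v - lo) / (hi - lo) for v in ed]
    maxmd = [(ed_used[i] + cos[i] + tc[i]) / 3.0 for i in range(m)]
    score = [2.0 * (weight * maxmr[i] + (1 - weight) * maxmd[i]) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-score[i], i))
    rank = [0] * m
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    return maxmr, ed, cos, tc, maxmd, score, rank


# ---------------------------------------------------------------------------
# Metrics


def metrics_oracle(tp, fp, tn, fn):
    total = tp + fp + tn + fn
    acc = (tp + tn) / total * 100.0
    sn = tp / (tp + fn) * 100.0 if tp + fn else 0.0
    sp = tn / (tn + fp) * 100.0 if tn + fp else 0.0
    den = (tp + fn) * (tn + fn) * (tp + fp) * (tn + fp)
    mcc = 0.0 if den == 0 else (tp * tn - fp * fn) / math.sqrt(den)
    return acc, sn, sp, mcc


def auc_oracle(labels, scores) -> float:
    """Mann-Whitney pairwise concordance with ties counted 1/2."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
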