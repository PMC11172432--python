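"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and explicit arithmetic,
deliberately sharing no code path with the package, so agreement between
the two is meaningful evidence of correctness.
"""

import math
from itertools import combinations

GROUPS = {}
for _g, _letters in enumerate(["AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C"], start=1):
    for _aa in _letters:
        GROUPS[_aa] = _g

REGION_WINDOWS = [
    (0.0, 0.25), (0.125, 0.375), (0.25, 0.5), (0.375, 0.625),
    (0.5, 0.75), (0.625, 0.875), (0.75, 1.0),
    (0.0, 0.75), (0.125, 0.875), (0.25, 1.0),
]


def brute_regions(seq):
    L = len(seq)
    return [seq[math.floor(s * L): math.floor(e * L)] for s, e in REGION_WINDOWS]


def brute_ctd(region):
    g = [GROUPS[aa] for aa in region]
    L = len(g)
    comp = [sum(1 for x in g if x == k) / L for k in range(1, 8)]
    trans = []
    for i, j in combinations(range(1, 8), 2):
        c = 0
        for t in range(L - 1):
            if (g[t], g[t + 1]) in ((i, j), (j, i)):
                c += 1
        trans.append(c / (L - 1) if L > 1 else 0.0)
    dist = []
    for k in range(1, 8):
        pos = [t + 1 for t in range(L) if g[t] == k]
        if not pos:
            dist.extend([0.0] * 5)
            continue
        n = len(pos)
        picks = [pos[0]]
        for q in (0.25, 0.5, 0.75):
            picks.append(pos[max(1, math.ceil(q * n)) - 1])
        picks.append(pos[-1])
        dist.extend(p / L for p in picks)
    return comp + trans + dist


def brute_ld(seq):
    seq = "".join(aa for aa in seq if aa in GROUPS)
    out = []
    for region in brute_regions(seq):
        out.extend(brute_ctd(region))
    return out


def brute_partitions():
    parts = []
    for quad in combinations(range(1, 8), 4):
        rest = sorted(set(range(1, 8)) - set(quad))
        a = {g: 0 for g in quad}
        for k, g in enumerate(rest):
            a[g] = k + 1
        parts.append(a)
    return parts


def brute_fvector(seq):
    seq = "".join(aa for aa in seq if aa in GROUPS)
    L = len(seq)
    out = []
    for part in brute_partitions():
        cls = [part[GROUPS[aa]] for aa in seq]
        totals = [cls.count(k) for k in range(4)]
        seen = [0, 0, 0, 0]
        xs, ys = [], []
        for c in cls:
            seen[c] += 1
            theta = (seen[c] / (totals[c] + 1) + c) * math.pi / 2
            xs.append(math.cos(theta))
            ys.append(math.sin(theta))
        f1 = sum(xs) / L
        f3 = sum(ys) / L
        if L > 1:
            f2 = sum((x - f1) ** 2 for x in xs) / (L - 1)
            f4 = sum((y - f3) ** 2 for y in ys) / (L - 1)
        else:
            f2 = f4 = 0.0
        out.extend([f1, f2, f3, f4])
    return out


def load_raw_properties(path):
    """Raw hydropathy tables from the packaged TSV (data, not code)."""
    h1, h2 = {}, {}
    lines = open(path).read().strip().splitlines()[1:]
    for line in lines:
        aa, a, b = line.split("\t")
        h1[aa] = float(a)
        h2[aa] = float(b)
    return h1, h2


def _standardize(table):
    vals = list(table.values())
    mu = sum(vals) / 20
    sd = math.sqrt(sum((v - mu) ** 2 for v in vals) / 20)
    return {aa: (v - mu) / sd for aa, v in table.items()}


AA20 = "ACDEFGHIKLMNPQRSTVWY"


def brute_apaacplus(seq, raw_h1, raw_h2, lam=30, w1=0.5, w2=0.5, plus=True):
    h1 = _standardize(raw_h1)
    h2 = _standardize(raw_h2)
    seq = "".join(aa for aa in seq if aa in h1)
    L = len(seq)
    freqs = [sum(1 for aa in seq if aa == r) / L for r in AA20]
    tau, ups = [], []
    for k in range(1, lam + 1):
        for h in (h1, h2):
            if L - k > 0:
                tau.append(sum(h[seq[i]] * h[seq[i + k]] for i in range(L - k)) / (L - k))
            else:
                tau.append(0.0)
        for h in (h1, h2):
            if L - 2 * k > 0:
                ups.append(
                    sum(h[seq[i]] * h[seq[i + k]] * h[seq[i + 2 * k]] for i in range(L - 2 * k))
                    / (L - 2 * k)
                )
            else:
                ups.append(0.0)
    if plus:
        denom = sum(freqs) + w1 * sum(tau) + w2 * sum(ups)
        return [f / denom for f in freqs] + [w1 * t / denom for t in tau] + [
            w2 * u / denom for u in ups
        ]
    denom = sum(freqs) + w1 * sum(tau)
    return [f / denom for f in freqs] + [w1 * t / denom for t in tau]


def brute_metrics(tp, fn, tn, fp):
    p, n = tp + fn, tn + fp
    acc = (tp + tn) / (p + n)
    sen = tp / p if p else 0.0
    spe = tn / n if n else 0.0
    pre = tp / (tp + fp) if tp + fp else 0.0
    npv = tn / (tn + fn) if tn + fn else 0.0
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    den = math.sqrt(p * n * (tp + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else 0.0
    return dict(acc=acc, sen=sen, spe=spe, pre=pre, npv=npv, f1=f1, mcc=mcc)


def brute_auroc(labels, scores):
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_auprc(labels, scores):
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    p_total = sum(labels)
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            if labels[order[j]] == 1:
                tp += 1
            else:
                fp += 1
            j += 1
        recall = tp / p_total
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def brute_select_threshold(labels, probs, lo=0.5, hi=1.0, step=0.001):
    best_t, best_f1 = None, -1.0
    t = lo
    grid = []
    k = 0
    while lo + k * step <= hi + step / 2:
        grid.append(lo + k * step)
        k += 1
    for t in grid:
        tp = sum(1 for y, p in zip(labels, probs) if y == 1 and p >= t)
        fp = sum(1 for y, p in zip(labels, probs) if y == 0 and p >= t)
        fn = sum(1 for y, p in zip(labels, probs) if y == 1 and p < t)
        f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
        if f1 > best_f1:
            best_t, best_f1 = t, f1
    return best_t
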