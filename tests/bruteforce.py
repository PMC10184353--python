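"""Straight-line, loop-based reference implementations used as oracles.

These re-derive every quantity with plain Python loops and scalar
arithmetic, independently of the package's vectorised code paths. Shared
contracts with the implementation are limited to the PRNG (numpy Generator
keyed per sample) and the percentile convention (numpy linear
interpolation), which are interface definitions rather than computation.
"""

from __future__ import annotations

import math
import zlib

import numpy as np


# ---------------------------------------------------------------------------
# nearest-template pipeline


def bf_bh(pvalues):
    """Step-up BH with the same canonical op order as the package claims:
    stable sort, (p*n)/rank, backward running minimum, clip at 1."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])  # stable for ties
    q = [(pvalues[order[i]] * n) / (i + 1) for i in range(n)]
    for i in range(n - 2, -1, -1):
        if q[i + 1] < q[i]:
            q[i] = q[i + 1]
    out = [0.0] * n
    for i in range(n):
        out[order[i]] = min(q[i], 1.0)
    return out


def bf_ntp(
    values,
    sample_ids,
    class_names,
    marker_positions,
    n_perm,
    fdr_threshold,
    seed,
    percentile=5.0,
):
    """Full nearest-template multi-label pipeline on a Z-scored matrix.

    ``values`` is genes x samples (list of columns accessed by index);
    ``marker_positions`` maps class name -> list of gene indices.
    Returns (distance, pvalue, fdr, primary, thresholds, label_sets) with
    per-sample dicts keyed by class.
    """
    n_genes = len(values)
    n_samples = len(sample_ids)
    distance = []
    pvalue = []
    for j in range(n_samples):
        x = [float(values[g][j]) for g in range(n_genes)]
        sq = 0.0
        for v in x:
            sq += v * v
        rng = np.random.default_rng(
            np.random.SeedSequence([int(seed), zlib.crc32(sample_ids[j].encode())])
        )
        drow = {}
        prow = {}
        for k in class_names:
            pos = marker_positions[k]
            m = len(pos)
            s_obs = 0.0
            for g in sorted(pos):
                s_obs += x[g]
            if sq == 0.0:
                d = 1.0
            else:
                d = 1.0 - s_obs / math.sqrt(sq * m)
            count = 0
            for _ in range(n_perm):
                drawn = rng.choice(n_genes, size=m, replace=False)
                s_null = 0.0
                for g in sorted(int(v) for v in drawn):
                    s_null += x[g]
                if s_null >= s_obs:
                    count += 1
            drow[k] = d
            prow[k] = (1 + count) / (1 + n_perm)
        distance.append(drow)
        pvalue.append(prow)
    fdr = []
    for j in range(n_samples):
        ps = [pvalue[j][k] for k in class_names]
        qs = bf_bh(ps)
        fdr.append({k: qs[i] for i, k in enumerate(class_names)})
    primary = []
    for j in range(n_samples):
        best = class_names[0]
        for k in class_names[1:]:
            if distance[j][k] < distance[j][best]:
                best = k
        primary.append(best if fdr[j][best] < fdr_threshold else "NC")
    thresholds = {}
    for k in class_names:
        scores = [
            1.0 - distance[j][k] for j in range(n_samples) if primary[j] == k
        ]
        if scores:
            # percentile convention is an interface constant, not computation
            thresholds[k] = float(np.percentile(np.array(scores), percentile))
        else:
            thresholds[k] = math.inf
    label_sets = []
    for j in range(n_samples):
        if primary[j] == "NC":
            label_sets.append(frozenset())
            continue
        labels = {primary[j]}
        for k in class_names:
            if k == primary[j]:
                continue
            if fdr[j][k] < fdr_threshold and (1.0 - distance[j][k]) >= thresholds[k]:
                labels.add(k)
        label_sets.append(frozenset(labels))
    return distance, pvalue, fdr, primary, thresholds, label_sets


# ---------------------------------------------------------------------------
# multi-label metrics


def bf_relaxed(pred_sets, ref_primary):
    hits = 0
    for s, r in zip(pred_sets, ref_primary):
        if r in s:
            hits += 1
    return hits / len(pred_sets)


def bf_hamming(pred_sets, ref_sets, k):
    total = 0
    for p, r in zip(pred_sets, ref_sets):
        for c in set(p) | set(r):
            if (c in p) != (c in r):
                total += 1
    return total / (len(pred_sets) * k)


def bf_subset(pred_sets, ref_sets):
    return sum(1 for p, r in zip(pred_sets, ref_sets) if set(p) == set(r)) / len(pred_sets)


def bf_jaccard(pred_sets, ref_sets):
    total = 0.0
    for p, r in zip(pred_sets, ref_sets):
        p, r = set(p), set(r)
        if not p and not r:
            total += 1.0
        else:
            total += len(p & r) / len(p | r)
    return total / len(pred_sets)


def bf_lrap(score_rows, ref_sets, class_names):
    """Label-ranking average precision; ties broken by class order."""
    per_sample = []
    for row, ref in zip(score_rows, ref_sets):
        if not ref:
            continue
        ranked = sorted(
            range(len(class_names)), key=lambda i: (-row[i], i)
        )
        rank_of = {class_names[c]: pos + 1 for pos, c in enumerate(ranked)}
        precs = []
        for t in ref:
            r = rank_of[t]
            above = sum(1 for u in ref if rank_of[u] <= r)
            precs.append(above / r)
        per_sample.append(sum(precs) / len(precs))
    return sum(per_sample) / len(per_sample)


# ---------------------------------------------------------------------------
# exact hypergeometric two-sided Fisher test


def bf_fisher(a, b, c, d):
    """Two-sided point-probability Fisher p and sample odds ratio (with the
    Haldane-Anscombe correction on zero cells) by exhaustive enumeration of
    the hypergeometric support."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c

    def log_comb(n_, k_):
        return math.lgamma(n_ + 1) - math.lgamma(k_ + 1) - math.lgamma(n_ - k_ + 1)

    def pmf(x):
        if x < max(0, c1 - (n - r1)) or x > min(r1, c1):
            return 0.0
        return math.exp(
            log_comb(r1, x) + log_comb(n - r1, c1 - x) - log_comb(n, c1)
        )

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = pmf(x)
        if px <= p_obs * (1.0 + 1e-7):  # tolerance for float ties, as is standard
            total += px
    p = min(total, 1.0)
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        aa, bb, cc, dd = a, b, c, d
    return p, (aa * dd) / (bb * cc)


# ---------------------------------------------------------------------------
# two-group log-rank by explicit risk-set tables


def bf_logrank(times_a, events_a, times_b, events_b):
    """Chi-square log-rank statistic from hand-built risk-set tables."""
    records = [(t, e, 0) for t, e in zip(times_a, events_a)] + [
        (t, e, 1) for t, e in zip(times_b, events_b)
    ]
    event_times = sorted({t for t, e, _ in records if e})
    observed_a = 0.0
    expected_a = 0.0
    variance = 0.0
    for t in event_times:
        at_risk = [(tt, ee, g) for tt, ee, g in records if tt >= t]
        n = len(at_risk)
        n_a = sum(1 for _, _, g in at_risk if g == 0)
        d = sum(1 for tt, ee, _ in at_risk if ee and tt == t)
        d_a = sum(1 for tt, ee, g in at_risk if ee and tt == t and g == 0)
        observed_a += d_a
        expected_a += d * n_a / n
        if n > 1:
            variance += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0
    return (observed_a - expected_a) ** 2 / variance
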