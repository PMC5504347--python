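"""Independent brute-force oracles.

Each oracle re-derives an expected result from first principles with a
different algorithm and code path than the implementation it checks, so
agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import re
from fractions import Fraction

import numpy as np


def brute_force_align(seq: str, refs: dict[str, str], max_mm: int = 2):
    """Exhaustive sense-strand Hamming scan; returns {(ref_id, start1, nm)}.

    N never matches anything (counts as a mismatch on either side).
    """
    seq = seq.upper()
    L = len(seq)
    found = []
    for rid, ref in refs.items():
        ref = ref.upper()
        for s0 in range(len(ref) - L + 1):
            nm = 0
            for o in range(L):
                a, b = ref[s0 + o], seq[o]
                if a != b or a == "N" or b == "N":
                    nm += 1
                    if nm > max_mm:
                        break
            if nm <= max_mm:
                found.append((rid, s0 + 1, nm))
    if not found:
        return set()
    best = min(f[2] for f in found)
    return {f for f in found if f[2] == best}


def exact_bin_means(coverage, n_bins: int):
    """Fractional-overlap binning with exact rational arithmetic."""
    cov = [Fraction(x).limit_denominator(10**9) for x in coverage]
    L = len(cov)
    width = Fraction(L, n_bins)
    means = []
    for j in range(n_bins):
        lo, hi = j * width, (j + 1) * width
        mass = Fraction(0)
        for i, c in enumerate(cov):
            a = max(Fraction(i), lo)
            b = min(Fraction(i + 1), hi)
            if b > a:
                mass += c * (b - a)
        means.append(mass / width if width > 0 else Fraction(0))
    return [float(m) for m in means]


def fine_grained_bin_means(coverage, n_bins: int, subdiv: int = 1000):
    """Numeric binning oracle that subdivides each nucleotide ``subdiv``-fold."""
    cov = np.repeat(np.asarray(coverage, dtype=float), subdiv)
    L = len(coverage)
    edges = np.linspace(0, L * subdiv, n_bins + 1)
    sub_idx = np.arange(L * subdiv)
    bin_of = np.clip(np.searchsorted(edges, sub_idx + 0.5) - 1, 0, n_bins - 1)
    mass = np.bincount(bin_of, weights=cov, minlength=n_bins) / subdiv
    width = L / n_bins
    return mass / width if width > 0 else np.zeros(n_bins)


def tmm_oracle(counts, logratio_trim=0.3, sum_trim=0.05):
    """Step-by-step trimmed-mean-of-M normalization, coded independently.

    Trimming is done by sorting and slicing index lists rather than rank
    comparisons; the first library is the reference and factors are rescaled
    to geometric mean 1.
    """
    x = np.asarray(counts, dtype=float)
    n_genes, n_lib = x.shape
    totals = x.sum(axis=0)
    factors = [1.0]
    for j in range(1, n_lib):
        obs, ref = x[:, j], x[:, 0]
        keep_idx = [g for g in range(n_genes) if obs[g] > 0 and ref[g] > 0]
        if not keep_idx:
            raise ValueError("no co-positive genes")
        p_obs = [obs[g] / totals[j] for g in keep_idx]
        p_ref = [ref[g] / totals[0] for g in keep_idx]
        m = [np.log2(po / pr) for po, pr in zip(p_obs, p_ref)]
        a = [0.5 * np.log2(po * pr) for po, pr in zip(p_obs, p_ref)]
        w = [
            1.0
            / (
                (totals[j] - obs[g]) / (totals[j] * obs[g])
                + (totals[0] - ref[g]) / (totals[0] * ref[g])
            )
            for g in keep_idx
        ]
        n = len(keep_idx)
        # ranks with midrank ties, reproduced without scipy
        def ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            r = [0.0] * n
            i = 0
            while i < n:
                jj = i
                while jj + 1 < n and vals[order[jj + 1]] == vals[order[i]]:
                    jj += 1
                avg = (i + jj) / 2 + 1
                for t in range(i, jj + 1):
                    r[order[t]] = avg
                i = jj + 1
            return r

        rm, ra = ranks(m), ranks(a)
        lo_m = int(np.floor(n * logratio_trim)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * sum_trim)) + 1
        hi_a = n + 1 - lo_a
        sel = [
            i
            for i in range(n)
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a
        ]
        if not sel:
            factors.append(1.0)
            continue
        num = sum(w[i] * m[i] for i in sel)
        den = sum(w[i] for i in sel)
        factors.append(float(2 ** (num / den)))
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


def fisher_two_sided_enumeration(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums P(X = k) over the support of the margins for every table whose
    probability is <= that of the observed table (with a tiny relative
    slack for float ties).
    """
    from math import comb

    n = a + b + c + d
    r = a + b
    csum = a + c
    lo = max(0, r + csum - n)
    hi = min(r, csum)
    denom = comb(n, csum)
    probs = {k: comb(r, k) * comb(n - r, csum - k) / denom for k in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


def codon_census_oracle(cds_map, codon, min_k=2):
    """Regex-based maximal-run census over the in-frame codon string."""
    hist: dict[int, int] = {}
    max_k = 0
    for seq in cds_map.values():
        seq = seq.upper()
        seq = seq[: len(seq) - len(seq) % 3]
        codstr = "|".join(seq[i : i + 3] for i in range(0, len(seq), 3))
        pattern = rf"(?:^|\|)((?:{codon})(?:\|{codon})*)(?:\||$)"
        for match in re.finditer(pattern, codstr):
            k = match.group(1).count("|") + 1
            if k >= min_k:
                hist[k] = hist.get(k, 0) + 1
                max_k = max(max_k, k)
    return dict(sorted(hist.items())), max_k
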