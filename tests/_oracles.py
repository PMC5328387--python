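"""Independent brute-force reference implementations used to validate the
package's optimised code paths.  Everything here is written directly from
first principles (exhaustive enumeration, closed forms) and shares no logic
with the implementation under test."""

from __future__ import annotations

import itertools
import math

# --- genetic code, written out by hand (standard table) -------------------

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def bf_codon_sites(codon):
    """Synonymous/nonsynonymous site counts for one codon: each of the nine
    single-nucleotide changes contributes 1/3 site, classed by effect;
    changes creating a stop are excluded entirely."""
    if GENETIC_CODE[codon] == "*":
        return 0.0, 0.0
    s = n = 0.0
    for pos in range(3):
        for nuc in "ACGT":
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if GENETIC_CODE[mut] == "*":
                continue
            if GENETIC_CODE[mut] == GENETIC_CODE[codon]:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def bf_codon_diffs(a, b):
    """Average synonymous/nonsynonymous step counts over all stop-free
    orderings of the single-site changes turning codon a into codon b.
    Returns None when every ordering passes through a stop."""
    positions = [i for i in range(3) if a[i] != b[i]]
    if not positions:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(positions):
        cur = a
        path_s = path_n = 0
        good = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if GENETIC_CODE[nxt] == "*":
                good = False
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if good:
            results.append((path_s, path_n))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


def bf_ng86(codon_pairs):
    """Brute-force Ps/Pn: returns (S, N, Sd, Nd, ps, pn)."""
    S = N = Sd = Nd = 0.0
    for a, b in codon_pairs:
        if GENETIC_CODE.get(a, "*") == "*" or GENETIC_CODE.get(b, "*") == "*":
            continue
        if any(c not in "ACGT" for c in a + b):
            continue
        diffs = bf_codon_diffs(a, b)
        if diffs is None:
            continue
        sa, na = bf_codon_sites(a)
        sb, nb = bf_codon_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += diffs[0]
        Nd += diffs[1]
    ps = Sd / S if S else None
    pn = Nd / N if N else None
    return S, N, Sd, Nd, ps, pn


# --- chaining oracle ------------------------------------------------------

def bf_chain_partition(hits, max_nt_gap, max_aa_gap, max_aa_overlap):
    """All hits belong to one (chrom, strand, protein) group, pre-sorted in
    reading order.  Enumerate every partition of the sequence into
    contiguous runs, keep those whose every adjacent pair satisfies the
    chaining constraints, and return the (unique) partition with the fewest
    runs, as a list of lists of hits."""

    def ok(prev, nxt):
        if prev.strand == "+":
            nt_gap = nxt.genome_start - prev.genome_end - 1
        else:
            nt_gap = prev.genome_start - nxt.genome_end - 1
        if nt_gap < 0 or nt_gap > max_nt_gap:
            return False
        if not (nxt.prot_start > prev.prot_start and nxt.prot_end > prev.prot_end):
            return False
        if nxt.prot_start - prev.prot_end - 1 > max_aa_gap:
            return False
        if prev.prot_end - nxt.prot_start + 1 > max_aa_overlap:
            return False
        return True

    n = len(hits)
    best = None
    # breakpoint bitmask: bit i set = break between hit i and i+1
    for mask in range(2 ** (n - 1)) if n else [0]:
        runs, cur = [], [hits[0]] if n else []
        valid = True
        for i in range(1, n):
            if mask & (1 << (i - 1)):
                runs.append(cur)
                cur = [hits[i]]
            else:
                if not ok(cur[-1], hits[i]):
                    valid = False
                    break
                cur.append(hits[i])
        if not valid:
            continue
        runs.append(cur)
        if best is None or len(runs) < len(best):
            best = runs
    return best


# --- region-scan oracle ---------------------------------------------------

def bf_scan_regions(partnered_flags, window, min_per_window, min_windows, boundary):
    """Naive region finder over a boolean partnered-model track.

    Returns a list of (first_model_index, last_model_index) for each called
    region, where the span runs from the first model of the first dense
    window to the last model of the last dense window of the merged run.
    """
    n = len(partnered_flags)
    if n < window:
        return []
    dense = []
    for i in range(n - window + 1):
        count = sum(1 for f in partnered_flags[i:i + window] if f)
        if count >= min_per_window:
            dense.append(i)
    # group dense windows: a gap of >= boundary consecutive non-dense windows splits
    groups = []
    for i in dense:
        if groups and i - groups[-1][-1] - 1 < boundary:
            groups[-1].append(i)
        else:
            groups.append([i])
    out = []
    for g in groups:
        if len(g) >= min_windows:
            out.append((g[0], g[-1] + window - 1))
    return out


# --- Welch's t-test, closed form ------------------------------------------

def bf_welch(a, b):
    """Welch's t statistic, Welch-Satterthwaite dof and two-tailed p-value
    from the textbook formulas (p via the regularised incomplete beta)."""
    from scipy.special import betainc

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    # two-tailed p from the t distribution via the incomplete beta function
    x = dof / (dof + t ** 2)
    p = betainc(dof / 2, 0.5, x)
    return t, dof, p
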