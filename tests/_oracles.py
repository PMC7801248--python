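"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive everything from first principles (Biopython
translation, exhaustive enumeration) rather than calling the package's own
counting code.
"""

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_sites(codon: str) -> float:
    """Synonymous site count by direct enumeration of the 9 mutants."""
    s = 0.0
    for pos in range(3):
        syn = stop = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if aa(mut) == "*":
                stop += 1
            elif aa(mut) == aa(codon):
                syn += 1
        if stop < 3:
            s += syn / (3 - stop)
    return s


def oracle_differences(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged difference counts by exhaustive path enumeration."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        cur, sd, nd, hit = a, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa(nxt) == "*" or aa(cur) == "*":
                hit = True
                nd += 1
            elif aa(nxt) == aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hit else clean).append((sd, nd))
    paths = clean or dirty
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def oracle_best_chain_score(anchors, orientation, max_gap, match, gap_penalty):
    """Maximum chain score over ALL valid chains, by exhaustive DFS.

    anchors: list of (ordinal_a, ordinal_b). Feasible only for ~<= 12 anchors.
    """
    n = len(anchors)
    best = 0.0

    def extend(last, score):
        nonlocal best
        best = max(best, score)
        for j in range(n):
            da = anchors[j][0] - anchors[last][0]
            db = anchors[j][1] - anchors[last][1]
            if not 0 < da <= max_gap:
                continue
            if orientation == "same" and not 0 < db <= max_gap:
                continue
            if orientation == "inverted" and not -max_gap <= db < 0:
                continue
            extend(j, score + match - gap_penalty * ((da - 1) + (abs(db) - 1)))

    for i in range(n):
        extend(i, match)
    return best


def oracle_cluster_windows(positions, window_bp, min_genes):
    """All maximal index runs [i, j] with span <= window and count >= min."""
    runs = []
    n = len(positions)
    for i in range(n):
        for j in range(i, n):
            if positions[j][1] - positions[i][0] <= window_bp:
                if j - i + 1 >= min_genes:
                    runs.append((i, j))
    # keep maximal runs only
    maximal = [r for r in runs
               if not any((a <= r[0] and r[1] <= b and (a, b) != r)
                          for a, b in runs)]
    merged = []
    for i, j in sorted(maximal):
        if merged and i <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], j)
        else:
            merged.append([i, j])
    return [tuple(m) for m in merged]
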