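"""Independent reference implementations used only to check the package.

These deliberately use different code paths from the implementation:
plain enumeration with Biopython translation for codon counting, and
networkx longest-path search on an explicit DAG for chain optimality.
"""

from itertools import permutations

from Bio.Data import CodonTable

_CODE = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_CODE.stop_codons)


def oracle_syn_sites(codon):
    """Fraction-of-one-step-changes synonymous site count for one codon."""
    aa = _CODE.forward_table[codon]
    total = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _CODE.forward_table[alt] == aa:
                total += 1 / 3
    return total


def oracle_codon_differences(c1, c2):
    """Average (syn, nonsyn) steps over all stop-free minimal paths, or None."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return (0.0, 0.0)
    totals = []
    for order in permutations(diff):
        cur, syn, non = c1, 0, 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                ok = False
                break
            if _CODE.forward_table[nxt] == _CODE.forward_table[cur]:
                syn += 1
            else:
                non += 1
            cur = nxt
        if ok:
            totals.append((syn, non))
    if not totals:
        return None
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )


def oracle_longest_chain(pairs, orientation, max_gap):
    """Optimal chain length by longest-path search on an explicit DAG."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(len(pairs)))
    for i, (ai, bi) in enumerate(pairs):
        for j, (aj, bj) in enumerate(pairs):
            if ai < aj <= ai + max_gap:
                if orientation > 0 and bi < bj <= bi + max_gap:
                    g.add_edge(i, j)
                if orientation < 0 and bj < bi <= bj + max_gap:
                    g.add_edge(i, j)
    return len(nx.dag_longest_path(g))


def oracle_geometric_mle(run_lengths):
    """Closed-form continuation-probability MLE: sum(k-1) / sum(k)."""
    total = sum(run_lengths)
    return (total - len(run_lengths)) / total
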