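"""Nei–Gojobori (1986) Ka/Ks estimation from aligned coding sequences.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of one-step nucleotide changes that preserve the encoded amino acid (universal
genetic code), averaged over the two sequences.  *Differences* in codons that
differ at several positions are averaged over all minimal substitution paths
with equal weight; path steps passing through a stop codon are excluded.
Proportions are corrected to distances with the Jukes–Cantor transform
d = -(3/4) ln(1 - (4/3) p), which is undefined (saturated) at p >= 3/4.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Data import CodonTable

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))

#: Ks values above this are treated as effectively saturated and are
#: excluded from downstream peak fitting.
KS_SOFT_CAP = 5.0


def _translate(codon: str) -> str | None:
    return _TABLE.forward_table.get(codon)


def _syn_site_count(codon: str) -> float:
    """Number of synonymous sites in a sense codon (0..3, fractional)."""
    aa = _translate(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt in STOP_CODONS:
                # a change to a stop is counted as nonsynonymous
                continue
            if _translate(alt) == aa:
                syn += 1
        total += syn / 3.0
    return total


_SYN_SITES: dict[str, float] = {c: _syn_site_count(c) for c in SENSE_CODONS}


def _path_differences(c1: str, c2: str) -> tuple[float, float] | None:
    """Average (synonymous, nonsynonymous) steps over all valid minimal paths.

    Returns None when every path is blocked by a stop codon.
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    syn_total = 0.0
    nonsyn_total = 0.0
    n_valid = 0
    for order in itertools.permutations(diff_pos):
        current = c1
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + c2[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if _translate(nxt) == _translate(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if blocked:
            continue
        syn_total += syn
        nonsyn_total += nonsyn
        n_valid += 1
    if n_valid == 0:
        return None
    return syn_total / n_valid, nonsyn_total / n_valid


_PAIR_CACHE: dict[tuple[str, str], tuple[float, float] | None] = {}


def _pair_differences(c1: str, c2: str) -> tuple[float, float] | None:
    key = (c1, c2) if c1 <= c2 else (c2, c1)
    try:
        return _PAIR_CACHE[key]
    except KeyError:
        result = _path_differences(*key)
        _PAIR_CACHE[key] = result
        return result


def jukes_cantor(p: float) -> float:
    """JC69 correction of a difference proportion; requires p < 3/4."""
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass
class KsResult:
    """Site/difference counts and corrected distances for one gene pair."""

    pair_id: str
    S: float = 0.0
    N: float = 0.0
    Sd: float = 0.0
    Nd: float = 0.0
    ps: float = float("nan")
    pn: float = float("nan")
    Ks: float = float("nan")
    Ka: float = float("nan")
    n_codons: int = 0
    status: str = "ok"
    reason: str = ""


def _clean(seq: str) -> str:
    return seq.upper().replace("U", "T")


def ng86(cds_a: str, cds_b: str, pair_id: str = "") -> KsResult:
    """NG86 Ka/Ks for two aligned, equal-length coding sequences.

    Codons containing a gap or ambiguity character in either sequence are
    skipped pairwise (neither contributes sites), which keeps
    S + N = 3 x (compared codon count) exact.  A length mismatch or internal
    stop codon yields a degenerate result rather than an exception, as does
    an empty alignment; saturation (p >= 3/4) is reported via status.
    """
    a, b = _clean(cds_a), _clean(cds_b)
    if len(a) != len(b):
        return KsResult(pair_id=pair_id, status="degenerate", reason="length mismatch")
    if len(a) % 3 != 0:
        return KsResult(
            pair_id=pair_id, status="degenerate", reason="length not a multiple of 3"
        )
    S = N = Sd = Nd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in STOP_CODONS or cb in STOP_CODONS:
            # trailing stop codons are tolerated, internal ones are not
            if i + 3 < len(a):
                return KsResult(
                    pair_id=pair_id, status="degenerate", reason="internal stop codon"
                )
            continue
        if ca not in _SYN_SITES or cb not in _SYN_SITES:
            continue  # gap or ambiguity: skip the codon pairwise
        diffs = _pair_differences(ca, cb)
        if diffs is None:
            continue  # all substitution paths blocked by stops
        sd, nd = diffs
        s_sites = 0.5 * (_SYN_SITES[ca] + _SYN_SITES[cb])
        S += s_sites
        N += 3.0 - s_sites
        Sd += sd
        Nd += nd
        n_codons += 1
    result = KsResult(pair_id=pair_id, S=S, N=N, Sd=Sd, Nd=Nd, n_codons=n_codons)
    if n_codons == 0:
        result.status = "degenerate"
        result.reason = "no comparable codons"
        return result
    result.ps = Sd / S if S > 0 else 0.0
    result.pn = Nd / N if N > 0 else 0.0
    if result.ps >= 0.75 or result.pn >= 0.75:
        result.status = "saturated"
        return result
    result.Ks = jukes_cantor(result.ps)
    result.Ka = jukes_cantor(result.pn)
    return result


def pairwise_ks_table(
    pairs: Iterable[tuple[str, str | None, str | None]]
) -> dict[str, KsResult]:
    """Batch NG86 over (pair_id, cds_a, cds_b) triples.

    Missing sequences are recorded as degenerate results; the run continues.
    """
    out: dict[str, KsResult] = {}
    for pair_id, a, b in pairs:
        if a is None or b is None:
            out[pair_id] = KsResult(
                pair_id=pair_id, status="degenerate", reason="missing sequence"
            )
        else:
            out[pair_id] = ng86(a, b, pair_id=pair_id)
    return out


def usable_ks(results: Mapping[str, KsResult]) -> dict[str, float]:
    """Extract Ks for ok results below the saturation guard (Ks <= 5)."""
    return {
        pid: r.Ks
        for pid, r in results.items()
        if r.status == "ok" and r.Ks <= KS_SOFT_CAP
    }
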