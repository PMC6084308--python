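"""Independent reference implementations used as test oracles.

Each oracle is deliberately written in the most literal way possible
(explicit state-space dynamic programming, textbook recursions, direct
graph search, a hand-typed codon table) so it shares no code path with
the package implementation it checks.
"""

from __future__ import annotations

from functools import lru_cache


def affine_dp_score(
    query: str,
    target: str,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal affine-gap global alignment score by explicit-state DP.

    State = (query consumed, target consumed, last operation), where the
    gap cost of extending is decided by the last operation — no separate
    gap matrices, no Gotoh shortcuts.
    """
    NEG = float("-inf")
    n, m = len(query), len(target)
    # last op: 0 = diagonal, 1 = gap-in-query (consumes target), 2 = gap-in-target
    best = [[dict() for _ in range(m + 1)] for _ in range(n + 1)]
    best[0][0][None] = 0.0
    for i in range(n + 1):
        for j in range(m + 1):
            for last, score in list(best[i][j].items()):
                if i < n and j < m:
                    s = match if query[i] == target[j] else mismatch
                    cell = best[i + 1][j + 1]
                    if score + s > cell.get(0, NEG):
                        cell[0] = score + s
                if j < m:
                    cost = gap_extend if last == 1 else gap_open
                    cell = best[i][j + 1]
                    if score + cost > cell.get(1, NEG):
                        cell[1] = score + cost
                if i < n:
                    cost = gap_extend if last == 2 else gap_open
                    cell = best[i + 1][j]
                    if score + cost > cell.get(2, NEG):
                        cell[2] = score + cost
    return max(best[n][m].values())


def levenshtein(a: str, b: str) -> int:
    """Textbook Wagner-Fischer edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def phase_components(
    het_positions: list[int], fragments: list[tuple[int, set[int]]]
) -> list[list[int]]:
    """Connected components of the het co-coverage graph by direct DFS.

    ``fragments`` is a list of (fragment id, set of het positions the
    fragment covers with a het-consistent allele).
    """
    adj = {p: set() for p in het_positions}
    for _, covered in fragments:
        cov = sorted(p for p in covered if p in adj)
        for a in cov:
            for b in cov:
                if a != b:
                    adj[a].add(b)
    seen = set()
    comps = []
    for p in sorted(het_positions):
        if p in seen:
            continue
        stack, comp = [p], []
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            comp.append(x)
            stack.extend(adj[x] - seen)
        comps.append(sorted(comp))
    return comps


_CODON_TABLE = {
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


def codon_scan_is_null(ref_cds: str, novel_cds: str) -> bool:
    """Premature-stop check by direct 5'->3' codon scanning.

    Truncates each CDS to a codon multiple, translates with a hand-typed
    codon table, and reports whether the novel protein stops strictly
    before the reference protein does (or loses its stop entirely after
    a frameshift).
    """

    def scan(cds: str) -> int | None:
        for k in range(0, len(cds) - len(cds) % 3, 3):
            if _CODON_TABLE[cds[k:k + 3]] == "*":
                return k // 3
        return None

    ref_stop = scan(ref_cds)
    novel_stop = scan(novel_cds)
    ref_len = ref_stop if ref_stop is not None else len(ref_cds) // 3
    if novel_stop is not None:
        return novel_stop < ref_len
    return len(novel_cds) % 3 != 0  # frameshift lost the stop codon


def classify_conflict_case(
    ref: str, sbs: frozenset, smrt: frozenset, in_homopolymer: bool
) -> str:
    """Exhaustive case analysis for one position's conflict category."""
    sbs_dev = sbs != {ref}
    smrt_dev = smrt != {ref}
    if not sbs_dev and not smrt_dev:
        return "none"
    if sbs_dev and smrt_dev and sbs == smrt:
        return "concordant_deviation"
    if smrt_dev and not sbs_dev:
        if "-" in smrt and in_homopolymer:
            return "homopolymer_indel"
        return "SMRT_only_deviation"
    return "SBS_only_deviation"


def rule_engine_oracle(categories: set, phasing_defined: bool) -> str:
    """The three workflow rules plus fixed precedence, stated directly.

    Rule 2 (repeat) dominates, then rule 3 (cluster+polish), then rule 1
    (submit the short-read consensus); no conflicts at all means the
    concordant sequence is submitted.
    """
    if "SBS_only_deviation" in categories:
        return "REPEAT_ANALYSIS"
    if not phasing_defined and (
        "homopolymer_indel" in categories or "phase_gap" in categories
    ):
        return "RUN_DR2S"
    if "SMRT_only_deviation" in categories or "homopolymer_indel" in categories:
        return "SUBMIT_SBS"
    return "SUBMIT_CONCORDANT"
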