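"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (explicit loops, full matrices, exhaustive
scans) and must stay independent of the code paths it checks.  The affine-gap
DP follows the package's *documented* deterministic conventions — diagonal
over deletion over insertion, gap closure over extension at ties, insertion
gaps re-opening only from non-insertion states — because path identity (not
just score identity) is part of the contract.
"""

from __future__ import annotations

NEG = float("-inf")


def naive_affine(query: str, ref: str, match: int, mismatch: int,
                 gap_open: int, gap_extend: int, mode: str):
    """Full-matrix affine-gap DP with explicit pointers.

    Returns (score, ops, ref_start, ref_end, query_start, query_end) where
    ops is a collapsed [(op, length)] list using M/X/I/D.
    Rows index the reference, columns the query.  ``global`` mode gives free
    end gaps on the reference side and consumes the query in full.
    """
    n, m = len(ref), len(query)
    local = mode == "local"
    H = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # horizontal: insertion
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # vertical: deletion
    Hp = [[NEG] * (m + 1) for _ in range(n + 1)]  # H without the E branch

    if local:
        for j in range(m + 1):
            H[0][j] = Hp[0][j] = 0
        for i in range(n + 1):
            H[i][0] = Hp[i][0] = 0
    else:
        H[0][0] = Hp[0][0] = 0
        for j in range(1, m + 1):
            H[0][j] = Hp[0][j] = -(gap_open + gap_extend * j)
        for i in range(1, n + 1):
            H[i][0] = Hp[i][0] = 0  # free leading reference gap

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if ref[i - 1] == query[j - 1] else -mismatch
            F[i][j] = max(F[i - 1][j] - gap_extend,
                          H[i - 1][j] - gap_open - gap_extend)
            hp = max(H[i - 1][j - 1] + s, F[i][j])
            if local:
                hp = max(hp, 0)
            Hp[i][j] = hp
            E[i][j] = max(E[i][j - 1] - gap_extend,
                          Hp[i][j - 1] - gap_open - gap_extend)
            H[i][j] = max(hp, E[i][j])

    if local:
        best, si, sj = 0, 0, 0
        for i in range(n + 1):
            for j in range(m + 1):
                if H[i][j] > best:
                    best, si, sj = H[i][j], i, j
        score = best
    else:
        best = max(H[i][m] for i in range(n + 1))
        si = next(i for i in range(n + 1) if H[i][m] == best)
        sj = m
        score = best

    ops: list[str] = []
    i, j, state = si, sj, "H"
    while True:
        if state == "H":
            if i == 0:
                if not local and j > 0:
                    ops.extend("I" * j)
                    j = 0
                break
            if j == 0:
                break
            s = match if ref[i - 1] == query[j - 1] else -mismatch
            if local and H[i][j] == 0 and max(H[i - 1][j - 1] + s, F[i][j]) < 0:
                break  # floor cell: the local alignment starts here
            if H[i][j] == H[i - 1][j - 1] + s:
                ops.append("M" if ref[i - 1] == query[j - 1] else "X")
                i, j = i - 1, j - 1
            elif H[i][j] == F[i][j]:
                state = "F"
            elif H[i][j] == E[i][j]:
                state = "E"
            else:  # local floor
                break
        elif state == "F":
            ops.append("D")
            if F[i][j] == H[i - 1][j] - gap_open - gap_extend:
                state = "H"
            i -= 1
        else:  # E
            ops.append("I")
            closed = E[i][j] == Hp[i][j - 1] - gap_open - gap_extend
            j -= 1
            if closed:
                state = "H"
            elif j == 0:
                break
    ops.reverse()
    collapsed: list[tuple[str, int]] = []
    for op in ops:
        if collapsed and collapsed[-1][0] == op:
            collapsed[-1] = (op, collapsed[-1][1] + 1)
        else:
            collapsed.append((op, 1))
    return score, collapsed, i, si, j, sj


def brute_force_sites(protospacer: str, pam_pattern: str, nuclease: str,
                      seed_length: int, ref_seq: str, max_mm=None,
                      require_seed=True):
    """Exhaustive both-strand guide-site scan; returns comparable tuples
    (strand, proto_start, proto_end, pam_start, pam_end, mismatches,
    seed_perfect) in forward coordinates."""
    from ampedit.refdb import reverse_complement

    iupac = {
        "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT",
        "S": "CG", "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
        "H": "ACT", "V": "ACG", "N": "ACGT",
    }
    L, P = len(protospacer), len(pam_pattern)
    out = []
    for strand in "+-":
        seq = ref_seq if strand == "+" else reverse_complement(ref_seq)
        nn = len(seq)
        for pos in range(nn):
            if nuclease == "cas9":
                proto_lo, pam_lo = pos, pos + L
            else:
                pam_lo, proto_lo = pos, pos + P
            proto_hi, pam_hi = proto_lo + L, pam_lo + P
            if max(proto_hi, pam_hi) > nn:
                continue
            pam = seq[pam_lo:pam_hi]
            if any(b not in iupac[p] for p, b in zip(pam_pattern, pam)):
                continue
            proto = seq[proto_lo:proto_hi]
            mm_positions = [k for k in range(L) if proto[k] != protospacer[k]]
            if nuclease == "cas9":
                seed_ok = all(k < L - seed_length for k in mm_positions)
            else:
                seed_ok = all(k >= seed_length for k in mm_positions)
            total = len(mm_positions)
            if require_seed and not seed_ok:
                continue
            if max_mm is not None and total > max_mm and not seed_ok:
                continue
            if strand == "+":
                coords = (proto_lo, proto_hi, pam_lo, pam_hi)
            else:
                coords = (nn - proto_hi, nn - proto_lo, nn - pam_hi, nn - pam_lo)
            out.append((strand, *coords, total, seed_ok))
    out.sort(key=lambda t: (t[1], t[0]))
    return out


def count_motif_all_offsets(peptide: str, motif: str) -> int:
    return sum(
        1
        for i in range(len(peptide) - len(motif) + 1)
        if peptide[i : i + len(motif)] == motif
    )


def enumerate_indel_placements(kind: str, pos: int, length: int,
                               inserted: str, ref: str):
    """All equivalent placements of one InDel by exhaustive haplotype test."""
    if kind == "deletion":
        target = ref[:pos] + ref[pos + length :]
        return [
            p
            for p in range(len(ref) - length + 1)
            if ref[:p] + ref[p + length :] == target
        ]
    # insertion: try every position; the inserted bases are forced by target
    target = ref[:pos] + inserted + ref[pos:]
    res = []
    for p in range(len(ref) + 1):
        candidate_seq = target[p : p + length]
        if ref[:p] + candidate_seq + ref[p:] == target:
            res.append((p, candidate_seq))
    return res
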