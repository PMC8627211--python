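"""Independent reference implementations used only to check the package.

These are deliberately naive (pure-Python loops, exhaustive enumeration)
and share no code with the implementations they validate.
"""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _score(a: str, b: str) -> int:
    if a == "X" or b == "X":
        return 0
    return int(_B62[a, b])


def sw_gotoh_local(q: str, s: str, gap_open: int = 11,
                   gap_extend: int = 1) -> int:
    """Textbook quadratic-space Gotoh local alignment.

    A gap of length L costs gap_open + L * gap_extend (BLAST convention),
    so opening a gap deducts gap_open + gap_extend for its first residue.
    """
    n, m = len(q), len(s)
    NEG = -(10 ** 9)
    first = gap_open + gap_extend
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (left)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject (up)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            diag = H[i - 1][j - 1] + _score(q[i - 1], s[j - 1])
            H[i][j] = max(0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def orfs_bruteforce(seq: str, min_len: int = 90,
                    starts=("ATG", "GTG", "TTG"),
                    stops=("TAA", "TAG", "TGA")):
    """All (start, end) forward-strand ORFs under the
    most-upstream-start-per-stop rule, by exhaustive enumeration."""
    out = []
    n = len(seq)
    for frame in range(3):
        codons = [(i, seq[i:i + 3]) for i in range(frame, n - 2, 3)]
        stop_positions = [i for i, c in codons if c in stops]
        prev_end = frame - 3
        for sp in stop_positions:
            # candidate starts strictly inside the stop-bounded segment
            cand = [i for i, c in codons
                    if prev_end < i <= sp - 3 and c in starts]
            if cand:
                start = min(cand)
                if sp + 3 - start >= min_len:
                    out.append((start, sp + 3))
            prev_end = sp
    return sorted(out)
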