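"""Smith-Waterman local alignment with affine gaps (Gotoh recursion).

Scoring defaults: match +1, mismatch -2; a gap of length k costs
``gap_open + (k - 1) * gap_extend`` (the first gapped column pays the open
penalty, each further column the extension).  ``N`` is treated as a
universal mismatch.  Used to decide whether an outlier SNP's flanking
window maps into a transcript under an identity/length criterion, so the
reported quantities are the aligned block coordinates and the identity
(matches / aligned columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LocalAlignment", "smith_waterman"]


@dataclass
class LocalAlignment:
    score: float
    query_start: int  # 0-based half-open on the query
    query_end: int
    subject_start: int
    subject_end: int
    n_matches: int
    n_columns: int  # aligned columns including gap columns
    aligned_query: str
    aligned_subject: str

    @property
    def identity(self) -> float:
        return self.n_matches / self.n_columns if self.n_columns else 0.0


def smith_waterman(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> LocalAlignment | None:
    """Optimal local alignment of two nucleotide sequences.

    Returns ``None`` when either sequence is empty or no positive-scoring
    alignment exists.  Ties break toward the smallest (query_end,
    subject_end) cell and, within a cell, prefer diagonal over gap moves.
    """
    q, s = query.upper(), subject.upper()
    n, m = len(q), len(s)
    if n == 0 or m == 0:
        return None

    neg = -np.inf
    H = np.zeros((n + 1, m + 1))  # best ending in a match/mismatch or start
    E = np.full((n + 1, m + 1), neg)  # gap in query (consume subject)
    F = np.full((n + 1, m + 1), neg)  # gap in subject (consume query)

    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    nmask_q = qa == ord("N")
    nmask_s = sa == ord("N")

    for i in range(1, n + 1):
        sub = np.where(
            (qa[i - 1] == sa) & ~nmask_q[i - 1] & ~nmask_s, match, mismatch
        )
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + gap_open, E[i, j - 1] + gap_extend)
            F[i, j] = max(H[i - 1, j] + gap_open, F[i - 1, j] + gap_extend)
            H[i, j] = max(0.0, H[i - 1, j - 1] + sub[j - 1], E[i, j], F[i, j])

    score = float(H.max())
    if score <= 0.0:
        return None
    end_i, end_j = np.unravel_index(int(np.argmax(H)), H.shape)

    # traceback
    aq: list[str] = []
    asub: list[str] = []
    i, j = int(end_i), int(end_j)
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            if H[i, j] == 0.0:
                break
            diag = H[i - 1, j - 1] + (
                match
                if q[i - 1] == s[j - 1] and q[i - 1] != "N"
                else mismatch
            )
            if H[i, j] == diag:
                aq.append(q[i - 1]); asub.append(s[j - 1])
                i -= 1; j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            aq.append("-"); asub.append(s[j - 1])
            if E[i, j] == E[i, j - 1] + gap_extend:
                j -= 1
            else:
                j -= 1
                state = "H"
        else:  # F
            aq.append(q[i - 1]); asub.append("-")
            if F[i, j] == F[i - 1, j] + gap_extend:
                i -= 1
            else:
                i -= 1
                state = "H"

    aq.reverse(); asub.reverse()
    n_cols = len(aq)
    n_matches = sum(
        1 for a, b in zip(aq, asub) if a == b and a not in ("-", "N")
    )
    return LocalAlignment(
        score=score,
        query_start=i,
        query_end=int(end_i),
        subject_start=j,
        subject_end=int(end_j),
        n_matches=n_matches,
        n_columns=n_cols,
        aligned_query="".join(aq),
        aligned_subject="".join(asub),
    )
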