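"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths (and Python's ``re``
engine for the motif oracle): the motif matcher below is a hand-written
recursive backtracker over the quadparser grammar, and the overlap oracle is
a plain O(n^2) pairwise scan.
"""

from __future__ import annotations


def g4_motifs_bruteforce(seq: str, g_run_min: int, loop_min: int,
                         loop_max: int, n_runs: int) -> list[tuple[int, int]]:
    """Leftmost, greedy, non-overlapping matches of the quadparser grammar
    ``(G-run >= k, then (loop, G-run) at least n_runs-1 times)`` on the plus
    strand, returned as (start, end) pairs.

    Exploration order mirrors greedy-with-backtracking semantics: prefer more
    (loop, run) repetitions; within a repetition prefer longer G-runs, then
    longer loops; the final run takes its maximal length.
    """
    s = seq.upper()
    n = len(s)
    # run_len[i] = length of the G-run starting at i
    run_len = [0] * (n + 1)
    for i in range(n - 1, -1, -1):
        run_len[i] = run_len[i + 1] + 1 if s[i] == "G" else 0
    r = n_runs - 1

    def attempt(i: int, done: int) -> int | None:
        """Return match end for the tail starting at i with ``done`` group
        repetitions already consumed, or None."""
        max_run = run_len[i]
        if max_run >= g_run_min:
            # try one more (run, loop) repetition, greedy: long runs first
            for g in range(max_run, g_run_min - 1, -1):
                j = i + g
                hi = min(loop_max, n - j)
                for loop in range(hi, loop_min - 1, -1):
                    end = attempt(j + loop, done + 1)
                    if end is not None:
                        return end
            # close with the final run (greedy: maximal) if enough repetitions
            if done >= r:
                return i + max_run
        return None

    out = []
    i = 0
    while i < n:
        if run_len[i] >= g_run_min:
            end = attempt(i, 0)
            if end is not None:
                out.append((i, end))
                i = end
                continue
        i += 1
    return out


def count_overlaps_bruteforce(query, subject, min_overlap: int = 1) -> list[int]:
    """O(n^2) per-query count of subjects sharing >= min_overlap bases."""
    counts = []
    for q in query:
        c = 0
        for t in subject:
            if q.chrom == t.chrom:
                if min(q.end, t.end) - max(q.start, t.start) >= min_overlap:
                    c += 1
        counts.append(c)
    return counts
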