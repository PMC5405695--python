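"""Independent re-implementations used as oracles by the test suite.

These are deliberately written from the textbook definitions, without using
the package or the libraries that back it.
"""


def sw_affine_oracle(q, s, matrix, gap_open=11, gap_extend=1):
    """Exhaustive affine-gap Smith-Waterman optimal local score."""
    n, m = len(q), len(s)
    neg = -1e9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in subject
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = matrix[q[i - 1], s[j - 1]]
            M[i][j] = max(
                0.0, sub + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            )
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def by_stepup_oracle(pvals):
    """Direct Benjamini-Yekutieli step-up: adjusted_i = min over j >= i of
    p_(j) * m * c(m) / j, capped at 1, returned in input order."""
    m = len(pvals)
    c = sum(1.0 / k for k in range(1, m + 1))
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m * c / rank)
        adjusted[i] = running
    return adjusted
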