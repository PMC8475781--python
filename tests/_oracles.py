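"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (flood fill, explicit sums of squares,
full enumeration) and shares no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """Connected components of a 3D boolean mask via explicit flood fill."""
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(v) for v in d)
        if (connectivity == 6 and order == 1) \
                or (connectivity == 18 and order <= 2) \
                or connectivity == 26:
            offsets.append(d)
    todo = {tuple(v) for v in np.argwhere(mask)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    return comps


def brute_force_topk(loc_t, eligible, k):
    """Top-k eligible indices by localizer t, ties by index order."""
    idx = [i for i in range(len(loc_t)) if eligible[i]]
    idx.sort(key=lambda i: (-loc_t[i], i))
    return idx[:k]


def rm_anova_2x2_ss(table: np.ndarray) -> dict:
    """First-principles sums-of-squares partition for a 2x2 within design.

    ``table`` columns are (A1B1, A1B2, A2B1, A2B2) with A = domain,
    B = difficulty; one row per subject.
    """
    n = table.shape[0]
    y = table.reshape(n, 2, 2)          # subject x A x B
    grand = y.mean()
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))
    m_as = y.mean(axis=2)
    m_bs = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = 2 * n * ((m_a - grand) ** 2).sum()
    ss_b = 2 * n * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = 2 * ((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2).sum()
    ss_bs = 2 * ((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2).sum()
    resid = (y - m_ab[None] - m_as[:, :, None] - m_bs[:, None, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = (resid ** 2).sum()
    dfe = n - 1
    return dict(
        F_domain=(ss_a / 1) / (ss_as / dfe),
        F_difficulty=(ss_b / 1) / (ss_bs / dfe),
        F_interaction=(ss_ab / 1) / (ss_abs / dfe),
    )


def rm_anova_oneway_gg(X: np.ndarray) -> dict:
    """One-way repeated-measures F and GG epsilon via orthonormal contrasts."""
    n, k = X.shape
    grand = X.mean()
    col = X.mean(axis=0)
    row = X.mean(axis=1)
    ss_eff = n * ((col - grand) ** 2).sum()
    ss_err = ((X - col[None] - row[:, None] + grand) ** 2).sum()
    F = (ss_eff / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    # orthonormal contrast basis orthogonal to the unit vector
    A = np.eye(k) - 1.0 / k
    q, _ = np.linalg.qr(A.T)
    C = q[:, : k - 1].T
    M = C @ np.cov(X, rowvar=False, ddof=1) @ C.T
    eps = np.trace(M) ** 2 / ((k - 1) * np.trace(M @ M))
    return dict(F=F, epsilon=float(np.clip(eps, 1.0 / (k - 1), 1.0)))


def sign_flip_p_enumeration(values: np.ndarray) -> float:
    """Exact two-sided sign-flip p for the mean, by full enumeration."""
    values = np.asarray(values, float)
    n = len(values)
    obs = abs(values.mean())
    count = 0
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        if abs((np.array(signs) * values).mean()) >= obs - 1e-12:
            count += 1
    return count / 2 ** n


def region_swap_p_enumeration(X: np.ndarray) -> float:
    """Exact two-region permutation p (mean difference), full enumeration."""
    n, k = X.shape
    assert k == 2
    obs = abs(X[:, 0].mean() - X[:, 1].mean())
    count = 0
    for swaps in itertools.product((False, True), repeat=n):
        perm = X.copy()
        for r, s in enumerate(swaps):
            if s:
                perm[r] = perm[r, ::-1]
        if abs(perm[:, 0].mean() - perm[:, 1].mean()) >= obs - 1e-12:
            count += 1
    return count / 2 ** n
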