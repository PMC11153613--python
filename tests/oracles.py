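"""Independent brute-force reference implementations used only by tests.

Every function here deliberately re-derives its quantity by a different
route than the package (explicit traces, textbook sums of squares, Newton
IRLS, counting-based midranks) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def symptom_threshold_bruteforce(items) -> bool:
    """Literal enumeration of the two clauses."""
    items = list(items)
    clause1 = any(s >= 5 for s in items)
    clause2 = sum(1 for s in items if s >= 4) >= 2
    return clause1 or clause2


def qc_pass_bruteforce(crlb, snr, fwhm) -> bool:
    return (crlb < 20.0) and (snr > 10.0) and (fwhm < 0.1)


def double_update_trace(choices, rewards, alpha, q0=(0.5, 0.5)):
    """Per-trial Q trajectory (values *at decision time*) as an array."""
    q = np.array(q0, dtype=float)
    traj = []
    for c, r in zip(choices, rewards):
        traj.append(q.copy())
        i, j = (0, 1) if c == 1 else (1, 0)
        q[i] = q[i] + alpha * (r - q[i])
        q[j] = q[j] + alpha * ((1 - r) - q[j])
    return np.array(traj)


def nll_trace(blocks, alpha, beta, eps=1e-12):
    """Step-by-step negative log-likelihood over (choices, rewards) blocks."""
    total = 0.0
    for choices, rewards in blocks:
        traj = double_update_trace(choices, rewards, alpha)
        for (q1, q2), c in zip(traj, choices):
            p1 = expit(beta * (q1 - q2))
            p = p1 if c == 1 else 1.0 - p1
            total -= np.log(max(p, eps))
    return float(total)


def nll_grid_search(blocks, n_alpha=200, n_beta=200, alpha_min=1e-3, beta_max=50.0):
    """Exhaustive grid minimum of the NLL over (alpha, beta).

    The Q trajectory depends on alpha only, so it is traced once per alpha
    and the likelihood is evaluated for every beta in one vectorized sweep
    (log1p(exp(.)) formulation, distinct from the package's scalar loop).
    """
    betas = np.linspace(0.0, beta_max, n_beta)
    best = np.inf
    for a in np.linspace(alpha_min, 1.0, n_alpha):
        total = np.zeros(n_beta)
        for choices, rewards in blocks:
            traj = double_update_trace(choices, rewards, a)
            qdiff = traj[:, 0] - traj[:, 1]
            # signed value difference: + favours the chosen option
            sign = np.where(np.asarray(choices) == 1, 1.0, -1.0)
            x = betas[None, :] * (qdiff * sign)[:, None]
            total += np.sum(np.logaddexp(0.0, -x), axis=0)
        best = min(best, float(total.min()))
    return best


def midranks(x):
    """Counting-based midranks (average ranks for ties), 1-based."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        out[i] = less + (equal + 1) / 2.0
    return out


def spearman_bruteforce(x, y):
    """Pearson product-moment formula applied to counting-based midranks."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def split_plot_anova_oracle(Y, groups):
    """Textbook cell-sums split-plot decomposition, balanced designs only.

    ``Y`` has shape (N, 2, 2): subjects x factor B levels x factor C levels;
    ``groups`` is a length-N label array with equal group sizes. Returns
    {effect: F}. Error terms: S(G) for the between effect; B x S(G) for B
    and G x B; C x S(G) for C and G x C; B x C x S(G) for the rest.
    """
    Y = np.asarray(Y, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    g = len(levels)
    N = Y.shape[0]
    n = N // g
    assert all(np.sum(groups == lev) == n for lev in levels), "oracle needs balance"

    GM = Y.mean()
    M_s = Y.mean(axis=(1, 2))
    M_g = {lev: Y[groups == lev].mean() for lev in levels}
    M_j = Y.mean(axis=(0, 2))
    M_k = Y.mean(axis=(0, 1))
    M_gj = {lev: Y[groups == lev].mean(axis=(0, 2)) for lev in levels}
    M_gk = {lev: Y[groups == lev].mean(axis=(0, 1)) for lev in levels}
    M_jk = Y.mean(axis=0)
    M_gjk = {lev: Y[groups == lev].mean(axis=0) for lev in levels}
    M_sj = Y.mean(axis=2)
    M_sk = Y.mean(axis=1)
    gs = np.array([np.where(levels == x)[0][0] for x in groups])

    ss_G = 4 * n * sum((M_g[lev] - GM) ** 2 for lev in levels)
    ss_SG = 4 * sum((M_s[i] - M_g[groups[i]]) ** 2 for i in range(N))
    ss_B = 2 * N * np.sum((M_j - GM) ** 2)
    ss_GB = 2 * n * sum(
        np.sum((M_gj[lev] - M_g[lev] - M_j + GM) ** 2) for lev in levels
    )
    ss_BSG = 2 * sum(
        np.sum((M_sj[i] - M_s[i] - M_gj[groups[i]] + M_g[groups[i]]) ** 2)
        for i in range(N)
    )
    ss_C = 2 * N * np.sum((M_k - GM) ** 2)
    ss_GC = 2 * n * sum(
        np.sum((M_gk[lev] - M_g[lev] - M_k + GM) ** 2) for lev in levels
    )
    ss_CSG = 2 * sum(
        np.sum((M_sk[i] - M_s[i] - M_gk[groups[i]] + M_g[groups[i]]) ** 2)
        for i in range(N)
    )
    ss_BC = N * np.sum((M_jk - M_j[:, None] - M_k[None, :] + GM) ** 2)
    ss_GBC = n * sum(
        np.sum(
            (
                M_gjk[lev]
                - M_gj[lev][:, None]
                - M_gk[lev][None, :]
                - M_jk
                + M_g[lev]
                + M_j[:, None]
                + M_k[None, :]
                - GM
            )
            ** 2
        )
        for lev in levels
    )
    ss_BCSG = sum(
        np.sum(
            (
                Y[i]
                - M_sj[i][:, None]
                - M_sk[i][None, :]
                - M_gjk[groups[i]]
                + M_s[i]
                + M_gj[groups[i]][:, None]
                + M_gk[groups[i]][None, :]
                - M_g[groups[i]]
            )
            ** 2
        )
        for i in range(N)
    )
    del gs
    df_err = N - g

    def F(ss_eff, df_eff, ss_err):
        return (ss_eff / df_eff) / (ss_err / df_err) if ss_err > 0 else 0.0

    return {
        "group": F(ss_G, g - 1, ss_SG),
        "B": F(ss_B, 1, ss_BSG),
        "group * B": F(ss_GB, g - 1, ss_BSG),
        "C": F(ss_C, 1, ss_CSG),
        "group * C": F(ss_GC, g - 1, ss_CSG),
        "B * C": F(ss_BC, 1, ss_BCSG),
        "group * B * C": F(ss_GBC, g - 1, ss_BCSG),
    }


def logistic_irls(X, y, tol=1e-12, max_iter=200):
    """Newton / iteratively-reweighted least squares for logistic regression.

    ``X`` includes the intercept column. Returns the coefficient vector.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        W = mu * (1 - mu)
        grad = X.T @ (y - mu)
        H = X.T @ (X * W[:, None])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def nagelkerke_scalar(l0, l1, n):
    """Direct scalar evaluation of the two pseudo-R² formulas."""
    import math

    r2_cs = 1.0 - math.exp(2.0 * (l0 - l1) / n)
    return r2_cs / (1.0 - math.exp(2.0 * l0 / n))
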