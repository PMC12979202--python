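import numpy as np
import pytest

from cmdcyto import CellularityModel, CmdNoiseModel, SimConfig, simulate_cohort


def small_sim_config(seed=0, n=6, **kwargs):
    """A fast two-centre cohort for plumbing tests."""
    defaults = dict(
        n_slides={"C": n, "K": n},
        cellularity=CellularityModel(median=250, sigma_log=0.4, minimum=50),
        seed=seed,
    )
    defaults.update(kwargs)
    return SimConfig(**defaults)


def planted_hpv_config(seed, n_slides=400, mean_neg=3.0, multiplier=10.0,
                       dispersion=0.8, median_cells=2000):
    """One-centre all-NILM cohort with a planted HPV effect on LSIL burden.

    HPV+ slides carry a ``multiplier``-fold larger negative-binomial LSIL
    burden; high CMD concentration keeps gating near-exact so downstream
    estimates target the planted count distributions.
    """
    from cmdcyto import AbnormalBurdenModel

    burden = AbnormalBurdenModel(
        means={"NILM": {"lsil": mean_neg, "hsil": 0.0, "adenocarcinoma": 0.0}},
        hpv_multiplier={"lsil": multiplier, "hsil": 1.0, "adenocarcinoma": 1.0},
        dispersion=dispersion,
    )
    return SimConfig(
        n_slides={"C": n_slides},
        diagnosis_mixture={"C": {"NILM": 1.0}},
        hpv_model={"NILM": 0.5},
        hpv_missing_rate=0.0,
        cellularity=CellularityModel(median=median_cells, sigma_log=0.6, minimum=100),
        abnormal_burden=burden,
        cmd_noise=CmdNoiseModel(concentration=80.0),
        seed=seed,
    )


@pytest.fixture(scope="session")
def tiny_cohort():
    slides, cells = simulate_cohort(small_sim_config(seed=11, n=4))
    return slides, cells


# ---------------------------------------------------------------------------
# Independent oracles (brute force; deliberately naive)


def brute_force_pairwise(ref, comp):
    """(U_ref, delta, AUC of comp-vs-ref) by explicit pair counting."""
    ref = np.asarray(ref, float)
    comp = np.asarray(comp, float)
    wins = losses = ties = 0
    for x in ref:
        for y in comp:
            if y > x:
                wins += 1
            elif y < x:
                losses += 1
            else:
                ties += 1
    n = ref.size * comp.size
    u_ref = losses + 0.5 * ties
    delta = (wins - losses) / n
    auc = (wins + 0.5 * ties) / n
    return u_ref, delta, auc


def brute_force_components(points, tol, gap):
    """Connected components of the detection-link relation by repeated BFS."""
    n = len(points)
    adj = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            (xi, yi, zi), (xj, yj, zj) = points[i], points[j]
            if np.hypot(xi - xj, yi - yj) <= tol and abs(zi - zj) <= gap + 1:
                adj[i].append(j)
                adj[j].append(i)
    comp = [-1] * n
    label = 0
    for start in range(n):
        if comp[start] != -1:
            continue
        stack = [start]
        comp[start] = label
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if comp[v] == -1:
                    comp[v] = label
                    stack.append(v)
        label += 1
    return comp


def nb_pmf(mean, r, n_max):
    from scipy.stats import nbinom

    return nbinom.pmf(np.arange(n_max + 1), r, r / (r + mean))


def planted_nb_auc_delta(mean_neg, mean_pos, r, tail=1e-9):
    """Exact P(pos > neg) +/- ties over two negative-binomial laws."""
    from scipy.stats import nbinom

    n_max = int(max(nbinom.ppf(1 - tail, r, r / (r + m)) for m in (mean_neg, mean_pos)))
    p_neg = nb_pmf(mean_neg, r, n_max)
    p_pos = nb_pmf(mean_pos, r, n_max)
    cdf_neg = np.cumsum(p_neg)
    # P(pos > neg) = sum_k P(pos = k) P(neg <= k-1)
    p_gt = float(np.sum(p_pos[1:] * cdf_neg[:-1]))
    p_eq = float(np.sum(p_pos * p_neg))
    auc = p_gt + 0.5 * p_eq
    delta = 2.0 * auc - 1.0
    return auc, delta, (p_neg, p_pos)


def auc_estimator_sd(p_neg, p_pos, n_neg, n_pos):
    """Exact SD of the empirical AUC over two discrete planted laws
    (two-sample U-statistic / Hanley-McNeil variance)."""
    cdf_neg = np.cumsum(p_neg)
    cdf_pos = np.cumsum(p_pos)
    surv_neg = 1.0 - cdf_neg
    surv_pos = 1.0 - cdf_pos
    # h(x, y) = 1[y > x] + 0.5 * 1[y = x]
    k = p_neg.size
    g_pos = np.empty(k)  # E_x h(x, y) as a function of y
    g_neg = np.empty(k)  # E_y h(x, y) as a function of x
    for v in range(k):
        g_pos[v] = (cdf_neg[v - 1] if v > 0 else 0.0) + 0.5 * p_neg[v]
        g_neg[v] = surv_pos[v] + 0.5 * p_pos[v]
    theta = float(np.sum(p_pos * g_pos))
    # h takes values {0, 1/2, 1}: E h^2 = P(>) + P(=)/4
    p_gt = float(np.sum(p_pos * np.r_[0.0, cdf_neg[:-1]]))
    p_eq = float(np.sum(p_pos * p_neg))
    var_h = (p_gt + 0.25 * p_eq) - theta**2
    var_g_pos = float(np.sum(p_pos * g_pos**2)) - theta**2
    var_g_neg = float(np.sum(p_neg * g_neg**2)) - theta**2
    var = (
        var_h + (n_pos - 1) * var_g_neg + (n_neg - 1) * var_g_pos
    ) / (n_neg * n_pos)
    return float(np.sqrt(var))
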