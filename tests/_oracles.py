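"""Independent oracles used by the test suite.

The TMFA oracle never touches the package's MILP compiler: it enumerates
all admissible direction assignments (forward / reverse / off per
thermodynamically constrained reaction) and solves each induced LP directly
with scipy.optimize.linprog, rebuilding the ΔrG′ coefficients from the raw
thermodynamic data.  The exact rank-sum oracle enumerates group labelings
directly.
"""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import scipy.optimize
import scipy.stats

LN10 = math.log(10.0)

F_STATE, R_STATE, O_STATE = "F", "R", "O"


def _drg_coefs(rid, model, thermo, config, conc_mets):
    """(const, lnc coef vector, ph_in coef, ph_out coef) for one reaction."""
    rxn = model.reactions[rid]
    const = thermo.dG0[rid]
    ph = 0.0
    if rid in thermo.transport:
        h, c = thermo.transport[rid]
        ph = c * config.F * config.psi_slope + h * LN10 * config.RT
        const += c * config.F * config.psi_intercept
    lnc = np.zeros(len(conc_mets))
    idx = {m: i for i, m in enumerate(conc_mets)}
    for mid, coef in rxn.stoichiometry.items():
        met = model.metabolites[mid]
        if met.artificial or met.formula == "H2O" or (met.formula == "H" and met.charge == 1):
            continue
        lnc[idx[mid]] += config.RT * coef
    return const, lnc, -ph, ph


def _admissible_states(lb, ub):
    states = []
    if ub > 0:
        states.append(F_STATE)
    if lb < 0:
        states.append(R_STATE)
    if lb <= 0 <= ub:
        states.append(O_STATE)
    return states


def enumerate_tmfa(problem, objective, sense="max"):
    """Exhaustive direction enumeration + LP solve.

    Returns (best_value or None, {pattern: value or None}) where a pattern
    is a tuple of (reaction id, state) over constrained reactions and the
    value is the LP optimum under that fixed assignment (None if the LP is
    infeasible).
    """
    model = problem.model
    thermo = problem.thermo
    config = problem.config
    constrained = problem.constrained_reactions()
    conc_mets = problem.concentration_metabolites()

    rxn_ids = list(model.reactions)
    n_r = len(rxn_ids)
    n_c = len(conc_mets)
    n = n_r + n_c + 2  # v..., lnc..., ph_in, ph_out
    r_idx = {rid: i for i, rid in enumerate(rxn_ids)}

    # steady state
    A_eq = np.zeros((len(model.metabolites), n))
    for j, rid in enumerate(rxn_ids):
        for mid, coef in model.reactions[rid].stoichiometry.items():
            A_eq[list(model.metabolites).index(mid), j] += coef
    b_eq = np.zeros(A_eq.shape[0])

    c_vec = np.zeros(n)
    for rid, coef in objective.items():
        c_vec[r_idx[rid]] += coef
    if sense == "max":
        c_vec = -c_vec

    base_bounds = []
    for rid in rxn_ids:
        base_bounds.append(problem.flux_bounds(rid))
    for mid in conc_mets:
        lo, hi = problem.conc_bounds(mid)
        base_bounds.append((math.log(lo), math.log(hi)))
    base_bounds.append(config.pH_in_bounds)
    base_bounds.append(config.pH_out_bounds)

    drg = {rid: _drg_coefs(rid, model, thermo, config, conc_mets) for rid in constrained}
    eps = config.feasibility_epsilon

    state_options = [
        _admissible_states(*problem.flux_bounds(rid)) for rid in constrained
    ]

    best = None
    patterns = {}
    for states in product(*state_options):
        bounds = list(base_bounds)
        A_ub_rows, b_ub = [], []
        for rid, st in zip(constrained, states):
            j = r_idx[rid]
            lb, ub = bounds[j]
            const, lnc, phi, pho = drg[rid]
            if st == F_STATE:
                bounds[j] = (max(0.0, lb), max(0.0, ub))
                row = np.zeros(n)
                row[n_r : n_r + n_c] = lnc
                row[-2] = phi
                row[-1] = pho
                A_ub_rows.append(row)
                b_ub.append(-eps - const)
            elif st == R_STATE:
                bounds[j] = (min(0.0, lb), min(0.0, ub))
                row = np.zeros(n)
                row[n_r : n_r + n_c] = -lnc
                row[-2] = -phi
                row[-1] = -pho
                A_ub_rows.append(row)
                b_ub.append(-eps + const)
            else:
                bounds[j] = (0.0, 0.0)
        res = scipy.optimize.linprog(
            c_vec,
            A_ub=np.array(A_ub_rows) if A_ub_rows else None,
            b_ub=np.array(b_ub) if b_ub else None,
            A_eq=A_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
        key = tuple(zip(constrained, states))
        if res.status == 0:
            value = -res.fun if sense == "max" else res.fun
            patterns[key] = value
            if best is None or (sense == "max" and value > best) or (
                sense == "min" and value < best
            ):
                best = value
        else:
            patterns[key] = None
    return best, patterns


def exact_ranksum_p_oracle(x, y) -> float:
    """Two-sided permutation p for the rank-sum test via direct labeling count.

    Counts, over every way of labeling the pooled observations, how often
    the midrank sum of the first group deviates from its null mean at least
    as much as observed.  Uses a different enumeration strategy (boolean
    masks over positions) than the implementation under test.
    """
    from itertools import combinations

    pooled = np.concatenate([np.asarray(x, float), np.asarray(y, float)])
    ranks = scipy.stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mean_w = n1 * (n + 1) / 2.0
    obs = abs(ranks[:n1].sum() - mean_w)
    hits = total = 0
    for mask in combinations(range(n), n1):
        total += 1
        if abs(ranks[list(mask)].sum() - mean_w) >= obs - 1e-12:
            hits += 1
    return hits / total


def kruskal_H_oracle(groups) -> float:
    """Tie-corrected Kruskal–Wallis H from the definitional formula."""
    arrays = [np.asarray(g, float) for g in groups]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = scipy.stats.rankdata(pooled)
    # split the midranks back into groups
    H = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + len(a)]
        start += len(a)
        H += r.sum() ** 2 / len(a)
    H = 12.0 / (n * (n + 1)) * H - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return H / tie if tie > 0 else 0.0
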