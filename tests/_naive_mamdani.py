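"""Independent brute-force Mamdani implementation used as a test oracle.

Deliberately naive: pure-Python loops over rules, clauses and grid points,
no numpy vectorization and no code shared with the engine module.  Given the
same membership-function parameters and grid resolution it must agree with
the package engine to floating-point accuracy.
"""

from __future__ import annotations


def naive_degree(shape, apex, left_foot, right_foot, x):
    if shape == "left_shoulder":
        if x <= apex:
            return 1.0
        if x >= right_foot:
            return 0.0
        return (right_foot - x) / (right_foot - apex)
    if shape == "right_shoulder":
        if x >= apex:
            return 1.0
        if x <= left_foot:
            return 0.0
        return (x - left_foot) / (apex - left_foot)
    if shape == "triangular":
        if x <= left_foot or x >= right_foot:
            return 0.0
        if x <= apex:
            return (x - left_foot) / (apex - left_foot) if apex > left_foot else 1.0
        return (right_foot - x) / (right_foot - apex) if right_foot > apex else 1.0
    raise ValueError(shape)


def _var_degree(var, mf_index, x):
    lo, hi = var.domain
    x = min(max(x, lo), hi)
    m = var.mfs[mf_index]
    return naive_degree(m.shape, m.apex, m.left_foot, m.right_foot, x)


def naive_classify(fis, record, grid_points=None):
    """Recompute (z, predicted_class) with naive loops and grid integration."""
    g = grid_points if grid_points is not None else fis.grid_points
    strengths = []
    for rule in fis.rule_base.rules:
        s = 1.0
        for feat, idx in rule.antecedent:
            s = min(s, _var_degree(fis.input_vars[feat], idx, float(record[feat])))
        strengths.append(s)

    lo, hi = fis.output_var.domain
    grid = [lo + i * (hi - lo) / (g - 1) for i in range(g)]
    num = 0.0
    den = 0.0
    for z in grid:
        mu = 0.0
        for rule, s in zip(fis.rule_base.rules, strengths):
            d = _var_degree(fis.output_var, rule.consequent, z)
            mu = max(mu, min(s, d))
        num += mu * z
        den += mu
    if den == 0.0:
        return (lo + hi) / 2.0, fis.majority_class
    z_star = num / den
    thr = (fis.output_var.mfs[0].apex + fis.output_var.mfs[-1].apex) / 2.0
    return z_star, (1 if z_star < thr else 2)
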