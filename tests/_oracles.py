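"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results through a different route than the
package (explicit scalar ledgers, exhaustive alignment enumeration) so that
agreement is evidence, not tautology.
"""

from __future__ import annotations

from cowgas.accounting import GAS_CONSTANT_ML_BAR, SPECIES


def ledger_balance(series):
    """Explicit scalar mole ledger for a measurement series.

    Walks the points one by one with plain dict arithmetic: convert each
    point's pressure to amounts, subtract the first point, credit every
    earlier withdrawal.  Mirrors the definition, not the implementation.
    """
    bottle = series.bottle
    temp = bottle.incubation_temperature
    r = bottle.gas_constant

    amounts = []
    removals = []
    volume = bottle.total_volume - bottle.initial_liquid_volume
    for point in series.points:
        xs = {sp: point.composition[sp] for sp in SPECIES}
        total_x = sum(xs.values())
        xs = {sp: x / total_x for sp, x in xs.items()}
        n_tot = point.pressure_before * volume / (r * temp)
        amounts.append({sp: xs[sp] * n_tot for sp in SPECIES})
        p_after = point.pressure_after
        if p_after is None:
            p_after = point.pressure_before * (1 - point.gas_sample_volume / volume)
        n_rem = (point.pressure_before - p_after) * volume / (r * temp)
        removals.append({sp: xs[sp] * n_rem for sp in SPECIES})
        volume += point.liquid_sample_volume

    q = []
    for i in range(len(series.points)):
        credited = {sp: sum(removals[k][sp] for k in range(i)) for sp in SPECIES}
        q.append(
            {sp: amounts[i][sp] - amounts[0][sp] + credited[sp] for sp in SPECIES}
        )
    return q


def brute_force_local_score(a: str, b: str, lookup, gap_open=11.0, gap_extend=1.0):
    """Best local alignment score by exhaustive enumeration.

    Enumerates every gapped alignment path whose first and last columns are
    substitutions (trimming terminal gaps never lowers the score, so the
    optimum is preserved) and scores affine gaps as open + (k-1)*extend.
    """
    best = 0.0
    m, n = len(a), len(b)

    def walk(i, j, score, last):
        nonlocal best
        # i, j index the *next* residues to consume
        if last == "M" and score > best:
            best = score
        if i < m and j < n:
            walk(i + 1, j + 1, score + lookup[(a[i], b[j])], "M")
        if last != "start":
            if j < n:
                cost = gap_extend if last == "E" else gap_open
                walk(i, j + 1, score - cost, "E")
            if i < m:
                cost = gap_extend if last == "F" else gap_open
                walk(i + 1, j, score - cost, "F")

    for i0 in range(m):
        for j0 in range(n):
            walk(i0 + 1, j0 + 1, lookup[(a[i0], b[j0])], "M")
    return best
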