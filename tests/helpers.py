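"""Shared fixtures-in-code and independent oracles for the test suite.

The oracles re-derive expected values by brute force / direct enumeration,
independently of the package's implementation paths.
"""

from __future__ import annotations

import itertools

from amstar_robis import (
    DesignMix,
    Instrument,
    PairedAssessment,
    Response,
    build_schema,
)

A2 = build_schema(Instrument.AMSTAR2)
RB = build_schema(Instrument.ROBIS)

ROBIS_TOKENS = ("Y", "PY", "PN", "N", "NI")


def make_assessment(
    review_id: str = "r1",
    has_ma: bool = True,
    design: DesignMix = DesignMix.RCT_ONLY,
    amstar: dict | None = None,
    robis: dict | None = None,
) -> PairedAssessment:
    """A fully valid all-positive assessment with targeted overrides."""
    a: dict = {}
    for it in A2.items:
        if it.ma_conditional and not has_ma:
            a[it.item_id] = Response.NA
        elif it.stratified_by_design and design is DesignMix.BOTH:
            a[it.item_id] = {"RCT": Response.Y, "NRSI": Response.Y}
        else:
            a[it.item_id] = Response.Y
    r = {i: Response.Y for i in RB.item_ids}
    if amstar:
        a.update(amstar)
    if robis:
        r.update(robis)
    return PairedAssessment(review_id=review_id, amstar=a, robis=r,
                            has_ma=has_ma, design_mix=design)


# ---------------------------------------------------------------------------
# Gwet coefficient oracles: direct arithmetic, no numpy, no shared code.


def gwet_oracle(pairs, categories, weights=None) -> float:
    """Brute-force Gwet coefficient from its defining sums."""
    n = len(pairs)
    q = len(categories)
    if weights is None:
        weights = {(a, b): 1.0 if a == b else 0.0
                   for a in categories for b in categories}
    pa = sum(weights[(a, b)] for a, b in pairs) / n
    pi = {
        k: sum((a == k) + (b == k) for a, b in pairs) / (2.0 * n)
        for k in categories
    }
    t_w = sum(weights.values())
    pe = t_w / (q * (q - 1)) * sum(p * (1.0 - p) for p in pi.values())
    return (pa - pe) / (1.0 - pe)


def jackknife_se_oracle(pairs, categories, weights=None) -> float:
    """Naive delete-one jackknife standard error."""
    n = len(pairs)
    loo = [
        gwet_oracle(pairs[:i] + pairs[i + 1:], categories, weights)
        for i in range(n)
    ]
    mean = sum(loo) / n
    return ((n - 1) / n * sum((v - mean) ** 2 for v in loo)) ** 0.5


def all_binary_configs(n_pairs: int = 4):
    """Every assignment of POS/NEG to both raters over n_pairs subjects."""
    sides = list(itertools.product("PN", repeat=n_pairs))
    for a_side in sides:
        for b_side in sides:
            yield [
                ("POS" if a == "P" else "NEG", "POS" if b == "P" else "NEG")
                for a, b in zip(a_side, b_side)
            ]


# ---------------------------------------------------------------------------
# Harmonization-rule oracles: table-driven re-derivations of the footnote
# conventions, written against raw tokens.


def _pos(token: str) -> bool:
    return token in ("Y", "PY")


def oracle_default(amstar_token: str, robis_token: str, amstar_py: bool):
    a = "POS" if (amstar_token == "Y" or (amstar_py and amstar_token == "PY")) else "NEG"
    b = "POS" if _pos(robis_token) else "NEG"
    return a, b


def oracle_rule_b(tokens: tuple[str, str, str, str]) -> str:
    n_pos = sum(_pos(t) for t in tokens)
    if n_pos == 4:
        return "Y"
    if _pos(tokens[2]) and _pos(tokens[3]):
        return "PY"
    return "N"


def oracle_rule_c(a9, r34: str, design: DesignMix):
    if design is DesignMix.BOTH:
        a_pos = _pos(a9["RCT"]) and _pos(a9["NRSI"])
    else:
        a_pos = _pos(a9)
    return ("POS" if a_pos else "NEG", "POS" if _pos(r34) else "NEG")


def oracle_rule_e(a11, r43: str, r44: str, has_ma: bool, design: DesignMix,
                  combine: str = "ALL"):
    if not has_ma:
        return None
    if design is DesignMix.BOTH:
        a_pos = a11["RCT"] == "Y" and a11["NRSI"] == "Y"
    else:
        a_pos = a11 == "Y"
    flags = [_pos(r43), _pos(r44)]
    r_pos = all(flags) if combine == "ALL" else any(flags)
    return ("POS" if a_pos else "NEG", "POS" if r_pos else "NEG")


def oracle_rule_f(a12: str, a13: str, r46: str, has_ma: bool):
    if has_ma:
        a_pos = a12 == "Y" and a13 == "Y"
    else:
        a_pos = a13 == "Y"
    return ("POS" if a_pos else "NEG", "POS" if _pos(r46) else "NEG")


def oracle_amstar_rating(critical_flaws: int, noncritical_flaws: int) -> str:
    """The four-way confidence rule, stated directly."""
    if critical_flaws > 1:
        return "CRITICALLY_LOW"
    if critical_flaws == 1:
        return "LOW"
    if noncritical_flaws > 1:
        return "MODERATE"
    return "HIGH"
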