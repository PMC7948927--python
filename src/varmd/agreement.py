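"""Binary call tables, combined predictor scores, and Cohen's κ benchmarking.

Sequence-based variant-effect predictors (SIFT, FATHMM, MutationTaster,
PROVEAN) each emit a binary affected/unaffected call per variant.  This
module measures chance-corrected agreement between raters with Cohen's κ,

    κ = (p_o − p_e) / (1 − p_e),

summarizes four predictors into a combined score (+1 per "unaffected", −1
per "affected"; negative → affected, zero → tie), and benchmarks predictions
— including MD-derived branch calls — against experimental activity labels
under explicit scenarios for how ambiguous ("possibly affected") variants
are counted.

The packaged OGG1 fixture ships the published predictor calls and the
experimental classification for the characterized variants.  Benchmarks
include the wild type as an item (experimentally unaffected, predicted
unaffected by every method) and exclude combined-score ties pairwise; both
choices are deliberate and documented, and the tie policy is selectable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "AFFECTED",
    "UNAFFECTED",
    "TIE",
    "NA",
    "KappaResult",
    "combined_score",
    "cohen_kappa",
    "kappa_matrix",
    "benchmark",
    "BenchmarkReport",
    "round3",
    "load_ogg1_calls",
    "load_ogg1_labels",
    "ogg1_scenarios",
    "OGG1_MD_DISTAL",
]

log = logging.getLogger(__name__)

AFFECTED = "affected"
UNAFFECTED = "unaffected"
TIE = "tie"
NA = "NA"
_BINARY = (AFFECTED, UNAFFECTED)

#: variants on the distal branch of the catalytic-geometry tree
OGG1_MD_DISTAL = frozenset({"I145M", "G202C", "V267M", "P291Q"})


def round3(x: float) -> float:
    """Round to 3 decimals with half-up ties, the convention used in the
    summary tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), ROUND_HALF_UP))


def combined_score(calls) -> tuple[int | None, str]:
    """Sum of four binary calls, +1 for unaffected and −1 for affected.

    Returns ``(score, derived_call)`` where the call is affected for a
    negative score, unaffected for a positive one, and a tie at zero.
    Any NA among the four calls yields an NA score.
    """
    calls = list(calls)
    if len(calls) != 4:
        raise ValueError(f"exactly 4 calls required, got {len(calls)}")
    if any(c not in _BINARY for c in calls):
        if all(c in _BINARY + (TIE, NA) for c in calls):
            return None, NA
        raise ValueError(f"unrecognized call among {calls}")
    score = sum(+1 if c == UNAFFECTED else -1 for c in calls)
    if score < 0:
        call = AFFECTED
    elif score > 0:
        call = UNAFFECTED
    else:
        call = TIE
    return score, call


@dataclass(frozen=True)
class KappaResult:
    """Cohen's κ with its 2×2 confusion counts.

    a: both affected; b: only the first rater affected; c: only the second
    rater affected; d: both unaffected.
    """

    a: int
    b: int
    c: int
    d: int

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def po(self) -> float:
        return (self.a + self.d) / self.n

    @property
    def pe(self) -> float:
        return (
            (self.a + self.b) * (self.a + self.c)
            + (self.c + self.d) * (self.b + self.d)
        ) / self.n**2

    @property
    def undefined(self) -> bool:
        return self.n < 2 or self.pe == 1.0

    @property
    def kappa(self) -> float:
        if self.undefined:
            return float("nan")
        return (self.po - self.pe) / (1.0 - self.pe)


def cohen_kappa(calls_a, calls_b) -> KappaResult:
    """Cohen's κ between two aligned binary call vectors.

    Items with a tie or NA in either vector are excluded (pairwise-complete
    analysis).  With fewer than two usable items, or when chance agreement
    is exactly 1 (both raters constant), κ is undefined and flagged.
    """
    va, vb = list(calls_a), list(calls_b)
    if len(va) != len(vb):
        raise ValueError("call vectors must be aligned")
    a = b = c = d = 0
    for x, y in zip(va, vb):
        if x not in _BINARY or y not in _BINARY:
            continue
        if x == AFFECTED and y == AFFECTED:
            a += 1
        elif x == AFFECTED:
            b += 1
        elif y == AFFECTED:
            c += 1
        else:
            d += 1
    res = KappaResult(a, b, c, d)
    if res.undefined:
        log.warning("kappa undefined (n=%d, pe=%s)", res.n, "1" if res.n else "-")
    return res


def kappa_matrix(call_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise κ between every pair of rater columns; diagonal 1 by
    convention, NaN where a pair has no usable items."""
    raters = list(call_table.columns)
    if len(raters) < 2:
        raise ValueError("need at least two raters")
    M = pd.DataFrame(np.eye(len(raters)), index=raters, columns=raters)
    for i, ra in enumerate(raters):
        for rb in raters[i + 1:]:
            res = cohen_kappa(call_table[ra], call_table[rb])
            M.loc[ra, rb] = M.loc[rb, ra] = res.kappa
    return M


@dataclass
class BenchmarkReport:
    """Per-method, per-scenario κ against experimental labels."""

    kappa: pd.DataFrame  # methods × scenarios, unrounded κ
    details: dict[tuple[str, str], KappaResult]
    wt_included: bool

    def rounded(self) -> pd.DataFrame:
        return self.kappa.map(round3)


def _resolve_labels(labels: dict[str, str], scenario: dict[str, str]) -> dict[str, str]:
    resolved = {}
    for item, lab in labels.items():
        if lab in _BINARY:
            resolved[item] = lab
        elif lab == "ambiguous":
            if item not in scenario:
                raise ValueError(f"scenario does not cover ambiguous item {item!r}")
            resolved[item] = scenario[item]
        else:
            raise ValueError(f"unrecognized experimental label {lab!r} for {item!r}")
    return resolved


def benchmark(
    calls: pd.DataFrame,
    labels: dict[str, str],
    scenarios: dict[str, dict[str, str]],
    *,
    md_affected: set[str] | None = None,
    wt_label: str = "WT",
    combined_raters: list[str] | None = None,
    tie_policy: str = "exclude",
) -> BenchmarkReport:
    """Benchmark predictor calls against experimental labels.

    ``calls`` is items × raters with affected/unaffected entries; it should
    contain the wild type as an item predicted unaffected by every rater
    (its absence is tolerated with a warning, but the summary then differs
    from the WT-inclusive convention).  ``labels`` maps items to
    affected / unaffected / ambiguous; every ``scenarios`` entry maps each
    ambiguous item to a binary label.

    For each scenario the report holds κ for every rater, for the combined
    four-predictor score (ties handled per ``tie_policy``: ``exclude``,
    ``affected`` or ``unaffected``), and — when ``md_affected`` is given —
    for the combined score augmented by ±1 according to membership in the
    MD-derived affected set, after which no tie is possible.
    """
    if tie_policy not in ("exclude", AFFECTED, UNAFFECTED):
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    items = [i for i in calls.index if i in labels]
    missing = sorted(set(labels) - set(calls.index))
    wt_included = wt_label in items
    if not wt_included:
        warnings.warn(
            f"wild type {wt_label!r} absent from the call table; "
            "computing without it"
        )
    if missing:
        log.info("labelled items without predictions ignored: %s", missing)
    raters = combined_raters or list(calls.columns)
    methods: dict[str, list[str]] = {r: list(calls.loc[items, r]) for r in calls.columns}

    if len(raters) == 4:
        comb_scores = {i: combined_score([calls.loc[i, r] for r in raters]) for i in items}
        comb_calls = []
        for i in items:
            _, call = comb_scores[i]
            if call == TIE and tie_policy != "exclude":
                call = tie_policy
            comb_calls.append(call)
        methods["combined"] = comb_calls

        if md_affected is not None:
            md_calls = []
            for i in items:
                score, _ = comb_scores[i]
                if score is None:
                    md_calls.append(NA)
                    continue
                score += -1 if i in md_affected else +1
                md_calls.append(AFFECTED if score < 0 else UNAFFECTED)
            methods["combined+md"] = md_calls
    elif md_affected is not None:
        log.info("combined score needs exactly 4 raters; %d given", len(raters))

    kappas = pd.DataFrame(index=list(methods), columns=list(scenarios), dtype=float)
    details: dict[tuple[str, str], KappaResult] = {}
    for sc_name, sc_map in scenarios.items():
        resolved = _resolve_labels({i: labels[i] for i in items}, sc_map)
        truth = [resolved[i] for i in items]
        for m_name, m_calls in methods.items():
            res = cohen_kappa(m_calls, truth)
            details[(m_name, sc_name)] = res
            kappas.loc[m_name, sc_name] = res.kappa
    return BenchmarkReport(kappas, details, wt_included)


# -- packaged OGG1 fixture ----------------------------------------------------


def _data_path(name: str):
    return resources.files("varmd.data").joinpath(name)


def load_ogg1_calls() -> pd.DataFrame:
    """Published binary predictor calls for the 20 sampled OGG1 variants plus
    the wild type (predicted unaffected by every method)."""
    with resources.as_file(_data_path("ogg1_calls.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("variant")


def load_ogg1_labels() -> dict[str, str]:
    """Experimental classification of the characterized OGG1 variants:
    affected {I145M, G202C, V267M}, ambiguous {R161W, S292N}, the rest of
    the purifiable set plus WT unaffected."""
    with resources.as_file(_data_path("ogg1_labels.csv")) as p:
        df = pd.read_csv(p)
    return dict(zip(df["variant"], df["label"]))


def ogg1_scenarios() -> dict[str, dict[str, str]]:
    """The two published ways of resolving the mildly affected variants:
    R161W and S292N counted as neutral, or as affected."""
    return {
        "ambiguous_neutral": {"R161W": UNAFFECTED, "S292N": UNAFFECTED},
        "ambiguous_affected": {"R161W": AFFECTED, "S292N": AFFECTED},
    }
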