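"""Deprotonation corrections, Eyring rates, and substrate comparison tables.

At physiological pH both substrates are predominantly protonated at the
ethylamino group, while the reactive species is neutral; the simulated
barriers are therefore raised by the deprotonation free energy

    dG_deprot = 2.303 kB T (pKa - pH),

applied to the water and enzyme barriers (gas-phase species are neutral and
reported uncorrected).  Barriers convert to transition-state-theory rate
constants k = (kB T / h) exp(-dG_act / kB T) with transmission coefficient 1,
and barrier differences to rate ratios exp(ddG / kB T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .constants import KB, KB_OVER_H, LN10

__all__ = [
    "ProtonationContext",
    "RateResult",
    "deprotonation_correction",
    "corrected_barrier",
    "eyring_rate",
    "rate_ratio",
    "assemble_comparison",
]


@dataclass
class ProtonationContext:
    """pKa/pH/temperature context of the deprotonation correction."""

    pKa: float
    pH: float = 7.4
    T: float = 300.0

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class RateResult:
    """Corrected barrier and TST rate; for pairs, the difference and ratio."""

    dg_act_corrected: float
    k: float
    T: float = 300.0
    ddg: float | None = None
    ratio: float | None = None
    log10_ratio: float | None = None

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant must be > 0")
        if self.ddg is not None and self.ratio is not None:
            expected = math.exp(self.ddg / (KB * self.T))
            if abs(self.ratio - expected) > 1e-9 * expected:
                raise ValueError("ratio is inconsistent with exp(ddg / kB T)")

    @classmethod
    def from_barrier(
        cls, dg_act_evb: float, ctx: ProtonationContext, ddg: float | None = None
    ) -> "RateResult":
        """Correct a barrier, convert to a rate, and (optionally) attach the
        pairwise difference and its rate ratio."""
        corrected = corrected_barrier(dg_act_evb, ctx)
        ratio = log10_ratio = None
        if ddg is not None:
            ratio, log10_ratio = rate_ratio(ddg, ctx.T)
        return cls(
            dg_act_corrected=corrected,
            k=eyring_rate(corrected, ctx.T),
            T=ctx.T,
            ddg=ddg,
            ratio=ratio,
            log10_ratio=log10_ratio,
        )


def deprotonation_correction(ctx: ProtonationContext) -> float:
    """dG_deprot = 2.303 kB T (pKa - pH), in kcal/mol."""
    return LN10 * KB * ctx.T * (ctx.pKa - ctx.pH)


def corrected_barrier(dg_act_evb: float, ctx: ProtonationContext) -> float:
    """EVB barrier plus the deprotonation free energy (kcal/mol)."""
    return dg_act_evb + deprotonation_correction(ctx)


def eyring_rate(dg_act: float, T: float = 300.0) -> float:
    """TST rate constant k = (kB T / h) exp(-dG_act / kB T), in s^-1."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    return KB_OVER_H * T * math.exp(-dg_act / (KB * T))


def rate_ratio(ddg: float, T: float = 300.0) -> tuple[float, float]:
    """(ratio, log10 ratio) implied by a barrier difference ddg (kcal/mol)."""
    if T <= 0:
        raise ValueError("temperature must be > 0")
    ratio = math.exp(ddg / (KB * T))
    return ratio, ddg / (LN10 * KB * T)


def assemble_comparison(
    results: dict[tuple[str, str], dict],
    contexts: dict[str, ProtonationContext],
) -> pd.DataFrame:
    """HIS-vs-NMH comparison table across environments.

    ``results`` maps (environment, substrate) to a dict with at least
    ``dg_act_evb`` and ``T`` (optionally ``dg_rxn``, ``sem``).  Corrections
    are applied in water and enzyme only.  Rows of kind ``substrate`` carry
    per-system barriers and rates; rows of kind ``difference`` carry
    ddG_act = dG_act(HIS) - dG_act(NMH) and the implied rate ratio
    k(NMH)/k(HIS).
    """
    if len({env for env, _ in results}) < 2:
        raise ValueError("comparison requires at least two environments")
    temps = {res["T"] for res in results.values()}
    if len(temps) != 1:
        raise ValueError(f"mixed temperatures in comparison: {sorted(temps)}")
    T = temps.pop()

    rows = []
    for (env, sub), res in sorted(results.items()):
        dg = float(res["dg_act_evb"])
        if env == "gas":
            corr = 0.0
        else:
            if sub not in contexts:
                raise ValueError(f"missing protonation context (pKa) for {sub}")
            ctx = contexts[sub]
            if ctx.T != T:
                raise ValueError("protonation context temperature differs from runs")
            corr = deprotonation_correction(ctx)
        corrected = dg + corr
        rows.append(
            {
                "kind": "substrate",
                "environment": env,
                "substrate": sub,
                "dg_evb": dg,
                "dg_deprot": corr,
                "dg_corrected": corrected,
                "dg_rxn": res.get("dg_rxn"),
                "sem": res.get("sem"),
                "k_per_s": eyring_rate(corrected, T),
            }
        )
    table = pd.DataFrame(rows)
    for env in sorted({e for e, _ in results}):
        pair = table[(table["environment"] == env) & (table["kind"] == "substrate")]
        if set(pair["substrate"]) >= {"HIS", "NMH"}:
            g_his = float(pair.loc[pair["substrate"] == "HIS", "dg_corrected"].iloc[0])
            g_nmh = float(pair.loc[pair["substrate"] == "NMH", "dg_corrected"].iloc[0])
            ddg = g_his - g_nmh
            ratio, log10_ratio = rate_ratio(ddg, T)
            sems = pair["sem"].astype(float)
            comb = math.sqrt(float((sems**2).sum())) if sems.notna().all() else None
            rows.append(
                {
                    "kind": "difference",
                    "environment": env,
                    "substrate": "HIS-NMH",
                    "dg_evb": None,
                    "dg_deprot": None,
                    "dg_corrected": ddg,
                    "dg_rxn": None,
                    "sem": comb,
                    "k_per_s": None,
                    "rate_ratio": ratio,
                    "log10_rate_ratio": log10_ratio,
                }
            )
    return pd.DataFrame(rows)
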