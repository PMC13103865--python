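"""ROESY cross-peak normalization and association classification.

Cross-peak volumes from a rotating-frame Overhauser experiment report
through-space proton proximity.  Within a xanthine, the methyl-to-CH
``[A-B]`` peak is the strongest and serves as the normalization reference
(set to exactly 1.0), making tables from different samples comparable.
The purely *inter*molecular xanthine-xanthine peaks ``[B-C]`` and ``[B-D]``
then gauge homo-association (xanthine-xanthine pairing); their maximum is
the *homo baseline* against which every xanthine-agent cross-peak is
judged.

The default verdict rule is volume-only: a system is
``hetero_preferred`` when at least half of the xanthine-agent peaks exceed
the baseline (and the strongest one does), ``homo_preferred`` when the
baseline dominates every hetero peak, and ``mixed`` otherwise.  Because
the propensity to form a pair also scales with concentration, an optional
concentration-aware rule rescales the homo baseline by the agent:xanthine
molality ratio (pair counts scale as [X]^2 vs [X][A]), which is how a
low-xanthine sample with a seemingly modest baseline can still be
homo-dominated.  No volume-to-distance conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REFERENCE_PAIR = ("A", "B")
HOMO_PAIRS = (("B", "C"), ("B", "D"))


def _canon(a: str, b: str) -> tuple[str, str]:
    a, b = str(a), str(b)
    return (a, b) if a <= b else (b, a)


def _collapse(peaks: pd.DataFrame) -> pd.DataFrame:
    """Canonicalize unordered pair keys; duplicate symmetric rows averaged."""
    required = {"site_a", "site_b", "volume"}
    if not required.issubset(peaks.columns):
        raise ValueError(f"peaks table needs columns {sorted(required)}")
    if (peaks["volume"] < 0).any():
        raise ValueError("cross-peak volumes must be non-negative")
    df = peaks.copy()
    pairs = [_canon(a, b) for a, b in zip(df["site_a"], df["site_b"])]
    df["site_a"] = [p[0] for p in pairs]
    df["site_b"] = [p[1] for p in pairs]
    return (df.groupby(["site_a", "site_b"], as_index=False)["volume"].mean())


def _volume(peaks: pd.DataFrame, pair: tuple[str, str]) -> float | None:
    a, b = _canon(*pair)
    row = peaks[(peaks["site_a"] == a) & (peaks["site_b"] == b)]
    return float(row["volume"].iloc[0]) if len(row) else None


def normalize(peaks: pd.DataFrame) -> pd.DataFrame:
    """Divide every volume by the ``[A-B]`` reference; it becomes exactly 1.

    Raises when the reference peak is missing or non-positive.  The
    operation is scale-invariant and idempotent.
    """
    df = _collapse(peaks)
    ref = _volume(df, REFERENCE_PAIR)
    if ref is None or ref <= 0:
        raise ValueError("table lacks a positive [A-B] reference cross-peak")
    df = df.copy()
    df["volume"] = df["volume"] / ref
    return df


@dataclass
class AssociationReport:
    """Evidence and verdict for one xanthine-agent system."""

    normalized: pd.DataFrame
    baseline: float                  # max of normalized [B-C], [B-D]
    baseline_effective: float        # after optional concentration rescaling
    hetero: pd.DataFrame             # xanthine-agent peaks with above-baseline flag
    n_hetero: int
    n_above: int
    max_hetero: float
    concentration_ratio: float | None  # xanthine : agent molality
    verdict: str                     # hetero_preferred | homo_preferred | mixed

    @property
    def homo_leaning(self) -> bool:
        """True unless the evidence decisively favours hetero-association."""
        return self.verdict != "hetero_preferred"


def _molecule_of(sites: pd.DataFrame) -> dict[str, str]:
    if not {"id", "molecule"}.issubset(sites.columns):
        raise ValueError("sites table needs columns id, molecule")
    return {str(r["id"]): str(r["molecule"]) for _, r in sites.iterrows()}


def classify_association(
    peaks: pd.DataFrame,
    sites: pd.DataFrame,
    concentrations: tuple[float, float] | None = None,
    concentration_aware: bool = False,
    majority: float = 0.5,
) -> AssociationReport:
    """Judge homo- vs hetero-association from a (raw or normalized) table.

    ``concentrations`` is ``(xanthine molality, agent molality)``; with
    ``concentration_aware=True`` the homo baseline is multiplied by the
    agent:xanthine ratio before comparison (equivalently, divided by the
    xanthine:agent ratio), putting the two pair propensities on a common
    concentration footing.  The ratio is always reported.
    """
    norm = normalize(peaks)
    molecule = _molecule_of(sites)
    homo_vols = [v for pair in HOMO_PAIRS if (v := _volume(norm, pair)) is not None]
    if not homo_vols:
        raise ValueError("table lacks the [B-C]/[B-D] homo-association peaks")
    baseline = max(homo_vols)
    mask = []
    for _, row in norm.iterrows():
        ma = molecule.get(row["site_a"])
        mb = molecule.get(row["site_b"])
        mask.append(ma is not None and mb is not None and {ma, mb} == {"xanthine", "agent"})
    hetero = norm[mask].copy()
    if hetero.empty:
        raise ValueError("no xanthine-agent cross-peaks in the table")
    ratio = None
    if concentrations is not None:
        m_x, m_a = concentrations
        if m_x <= 0 or m_a <= 0:
            raise ValueError("concentrations must be positive")
        ratio = m_x / m_a
    baseline_eff = baseline
    if concentration_aware:
        if ratio is None:
            raise ValueError("concentration_aware requires concentrations")
        baseline_eff = baseline / ratio
    hetero["above_baseline"] = hetero["volume"] > baseline_eff
    n_hetero = len(hetero)
    n_above = int(hetero["above_baseline"].sum())
    max_het = float(hetero["volume"].max())
    if n_above / n_hetero >= majority and max_het > baseline_eff:
        verdict = "hetero_preferred"
    elif baseline_eff >= max_het:
        verdict = "homo_preferred"
    else:
        verdict = "mixed"
    return AssociationReport(
        normalized=norm, baseline=baseline, baseline_effective=baseline_eff,
        hetero=hetero, n_hetero=n_hetero, n_above=n_above, max_hetero=max_het,
        concentration_ratio=ratio, verdict=verdict)


@dataclass
class RingInvolvement:
    """Mean normalized xanthine-agent volume per agent site, split by
    aromatic-ring membership."""

    per_site: pd.DataFrame        # site, aromatic, mean_volume, sorted descending
    aromatic_mean: float
    non_aromatic_mean: float


def ring_involvement(peaks: pd.DataFrame, sites: pd.DataFrame) -> RingInvolvement:
    """Rank agent sites by how strongly they contact xanthine protons.

    Requires an ``aromatic`` column in the sites table.  The aromatic vs
    non-aromatic aggregate means quantify whether the agent's ring face,
    rather than its tail, carries the contact — the stacking signature.
    """
    if "aromatic" not in sites.columns:
        raise ValueError("sites table needs an aromatic column")
    norm = normalize(peaks)
    molecule = _molecule_of(sites)
    aromatic = {str(r["id"]): bool(r["aromatic"]) for _, r in sites.iterrows()}
    vols: dict[str, list[float]] = {}
    for _, row in norm.iterrows():
        a, b = row["site_a"], row["site_b"]
        ma, mb = molecule.get(a), molecule.get(b)
        if ma is None or mb is None or {ma, mb} != {"xanthine", "agent"}:
            continue
        agent_site = a if ma == "agent" else b
        vols.setdefault(agent_site, []).append(float(row["volume"]))
    if not vols:
        raise ValueError("no xanthine-agent cross-peaks in the table")
    per_site = pd.DataFrame(
        [{"site": s, "aromatic": aromatic[s], "mean_volume": float(np.mean(v))}
         for s, v in vols.items()]
    ).sort_values("mean_volume", ascending=False).reset_index(drop=True)
    arom = per_site[per_site["aromatic"]]["mean_volume"]
    nonarom = per_site[~per_site["aromatic"]]["mean_volume"]
    return RingInvolvement(
        per_site=per_site,
        aromatic_mean=float(arom.mean()) if len(arom) else float("nan"),
        non_aromatic_mean=float(nonarom.mean()) if len(nonarom) else float("nan"))
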