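"""Synthetic data generators with recorded ground truth.

Every stage of the analysis can be exercised without any external download:
random proteins with controllable residue composition, ortholog sets with
per-site substitution noise (no indels by default, so position bookkeeping
stays trivial), per-residue score tables with *planted* site classes, and
noisy multi-predictor call sets with stated sensitivity/false-positive
rates. Each generator is a pure function of its parameters and a seed, and
returns the planted truth alongside the data so tests can check exact
recovery.

Planted potentials are drawn uniformly inside class-consistent intervals
kept ``epsilon/2`` away from every decision boundary, so recovery can never
flake on floating-point ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .conservation import ConservationProfile
from .crosstalk import Classification, CrosstalkParams, SiteScore
from .methylation import MethylationCallSet
from .seqio import Msa, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth recorded by the generators."""

    seed: int
    labels: dict[int, Classification] = field(default_factory=dict)
    conserved: frozenset[int] = frozenset()
    methyl_sites: frozenset[tuple[int, str]] = frozenset()
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_protein(
    length: int,
    composition: Mapping[str, float] | None = None,
    seed: int = 0,
    record_id: str = "synthetic",
) -> ProteinRecord:
    """Random protein with i.i.d. residues drawn from ``composition``.

    ``composition`` maps residues to probabilities summing to 1 (residues
    omitted get probability 0); ``None`` means uniform over the 20 standard
    residues.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if composition is None:
        probs = np.full(20, 1 / 20)
    else:
        bad = set(composition) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"composition contains non-standard residues {sorted(bad)}")
        probs = np.array([composition.get(r, 0.0) for r in AMINO_ACIDS], dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("composition probabilities must be >= 0 and sum to 1")
        probs = probs / probs.sum()
    rng = _rng(seed)
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=length, p=probs))
    return ProteinRecord(id=record_id, sequence=seq)


def gen_orthologs(
    record: ProteinRecord,
    n: int = 4,
    sub_rate: float = 0.05,
    seed: int = 0,
    indel_rate: float = 0.0,
) -> tuple[Msa, frozenset[int]]:
    """Simulated ortholog set: per-position substitutions, no indels by default.

    Each of the ``n`` orthologs independently substitutes each position with
    probability ``sub_rate`` (always to a *different* residue). Returns the
    gap-free alignment (query first) and the union of substituted positions
    — exactly the positions that fail strict-identity conservation.

    ``indel_rate > 0`` additionally deletes positions from orthologs (for
    exercising gapped position mapping); deleted positions join the truth
    set, since a deletion also breaks strict conservation.
    """
    if n < 1:
        raise ValueError("need at least one ortholog")
    if not 0 <= sub_rate <= 1:
        raise ValueError("sub_rate must be in [0, 1]")
    rng = _rng(seed)
    length = len(record)
    aa = np.array(list(AMINO_ACIDS))
    mutated: set[int] = set()
    rows = [(record.id, record.sequence)]
    for i in range(n):
        chars = list(record.sequence)
        hit = rng.random(length) < sub_rate
        for idx in np.nonzero(hit)[0]:
            current = chars[idx]
            choices = [r for r in AMINO_ACIDS if r != current]
            chars[idx] = choices[rng.integers(len(choices))]
            mutated.add(int(idx) + 1)
        if indel_rate > 0:
            gaps = rng.random(length) < indel_rate
            for idx in np.nonzero(gaps)[0]:
                chars[idx] = "-"
                mutated.add(int(idx) + 1)
        rows.append((f"{record.id}_ortho{i + 1}", "".join(chars)))
    return Msa(rows=tuple(rows), ref_id=record.id), frozenset(mutated)


_CLASS_CHANNELS: dict[Classification, tuple[str, str | None]] = {
    Classification.YY_POSITIVE: ("above", "above"),
    Classification.PHOSPHO_ONLY: ("above", "below"),
    Classification.GLYC_ONLY: ("below", "above"),
    Classification.NONE: ("below", "below"),
}


def _draw_in_category(rng: np.random.Generator, category: str, thr: float, eps: float) -> float:
    """Uniform draw inside the category's interval, epsilon/2 off each boundary."""
    if category == "above":
        lo, hi = thr + eps / 2, 1.0
    elif category == "near":
        lo, hi = thr - 0.75 * eps, thr - 0.25 * eps
    else:  # below
        lo, hi = 0.0, max(thr - 1.5 * eps, 0.0)
    if not lo < hi:
        raise ValueError(f"empty interval for category {category!r} (thr={thr}, eps={eps})")
    return float(rng.uniform(lo, hi))


def gen_site_scores(
    record: ProteinRecord,
    planted: Mapping[Classification | str, int],
    params: CrosstalkParams | None = None,
    seed: int = 0,
    conserved_positions: frozenset[int] | None = None,
    sa_missing_rate: float = 0.3,
) -> tuple[list[SiteScore], SyntheticTruth]:
    """Plant sites of requested classes on a protein's Ser/Thr positions.

    Potentials are drawn so that each planted site satisfies its class
    definition with margin ``epsilon/2`` from every decision boundary.
    False-negative Yin Yang sites are planted only on conserved positions
    (their definition requires conservation); when ``conserved_positions``
    is None, all planted positions are marked conserved in the returned
    truth except that NONE/PHOSPHO_ONLY/GLYC_ONLY/YY_POSITIVE sites are
    randomly split so conservation carries no class information.
    """
    params = params or CrosstalkParams()
    planted = {Classification(k): int(v) for k, v in planted.items()}
    if planted.get(Classification.YY_FALSE_NEGATIVE, 0) > 0 and params.epsilon <= 0:
        raise ValueError("epsilon must be > 0 to plant false-negative Yin Yang sites")
    rng = _rng(seed)
    eligible = [i + 1 for i, r in enumerate(record.sequence) if r in "ST"]
    total = sum(planted.values())
    if total > len(eligible):
        raise ValueError(
            f"cannot plant {total} sites: only {len(eligible)} Ser/Thr positions available"
        )
    order = [int(p) for p in rng.permutation(eligible)]
    n_fn = planted.get(Classification.YY_FALSE_NEGATIVE, 0)
    if conserved_positions is not None and n_fn:
        cons_eligible = [p for p in order if p in conserved_positions]
        if len(cons_eligible) < n_fn:
            raise ValueError(
                f"false-negative Yin Yang sites require conserved positions: need {n_fn}, "
                f"only {len(cons_eligible)} conserved Ser/Thr available"
            )

    thr_p, thr_g, eps = params.phos_threshold, 0.5, params.epsilon
    sites: list[SiteScore] = []
    labels: dict[int, Classification] = {}
    conserved: set[int] = set()
    available = list(order)

    def take(pred=None) -> int:
        for i, p in enumerate(available):
            if pred is None or pred(p):
                return available.pop(i)
        raise ValueError("insufficient eligible residues for the requested planting")
    # FN first: they may be constrained to conserved positions
    for cls in (
        Classification.YY_FALSE_NEGATIVE,
        Classification.YY_POSITIVE,
        Classification.PHOSPHO_ONLY,
        Classification.GLYC_ONLY,
        Classification.NONE,
    ):
        for _ in range(planted.get(cls, 0)):
            if cls is Classification.YY_FALSE_NEGATIVE and conserved_positions is not None:
                pos = take(lambda p: p in conserved_positions)
            else:
                pos = take()
            if cls is Classification.YY_FALSE_NEGATIVE:
                # strong channel chosen at random: (above, near) or (near, above)
                if rng.random() < 0.5:
                    p_cat, g_cat = "above", "near"
                else:
                    p_cat, g_cat = "near", "above"
                conserved.add(pos)
            else:
                p_cat, g_cat = _CLASS_CHANNELS[cls]
                if conserved_positions is not None:
                    if pos in conserved_positions:
                        conserved.add(pos)
                elif rng.random() < 0.5:
                    conserved.add(pos)
            sa = None if rng.random() < sa_missing_rate else float(rng.uniform(0, 3))
            sites.append(
                SiteScore(
                    position=pos,
                    residue=record.residue(pos),
                    phos=_draw_in_category(rng, p_cat, thr_p, eps),
                    glyc=_draw_in_category(rng, g_cat, thr_g, eps),
                    phos_threshold=thr_p,
                    glyc_threshold=thr_g,
                    sa=sa,
                )
            )
            labels[pos] = cls
    sites.sort(key=lambda s: s.position)
    truth = SyntheticTruth(
        seed=seed,
        labels=labels,
        conserved=frozenset(conserved),
        params={
            "phos_threshold": thr_p,
            "glyc_threshold": thr_g,
            "epsilon": eps,
            "planted": {c.value: n for c, n in planted.items()},
        },
    )
    return sites, truth


def gen_callsets(
    true_sites: frozenset[tuple[int, str]] | Sequence[tuple[int, str]],
    n_predictors: int = 3,
    sensitivity: float = 0.9,
    fpr: float = 0.01,
    eligible_positions: Sequence[tuple[int, str]] = (),
    seed: int = 0,
) -> list[MethylationCallSet]:
    """Noisy per-predictor methylation call sets.

    Each predictor independently includes each true site with probability
    ``sensitivity`` and each non-site eligible position with probability
    ``fpr``.
    """
    if not 0 <= sensitivity <= 1 or not 0 <= fpr <= 1:
        raise ValueError("sensitivity and fpr must be in [0, 1]")
    rng = _rng(seed)
    truth = sorted(set(true_sites))
    negatives = sorted(set(eligible_positions) - set(truth))
    out = []
    for i in range(n_predictors):
        calls = {site for site in truth if rng.random() < sensitivity}
        calls |= {site for site in negatives if rng.random() < fpr}
        out.append(MethylationCallSet(predictor=f"predictor{i + 1}", calls=frozenset(calls)))
    return out


def profile_from_truth(record: ProteinRecord, mutated: frozenset[int]) -> ConservationProfile:
    """The conservation profile implied by a generator truth set (for checks)."""
    flags = tuple(p not in mutated for p in range(1, len(record) + 1))
    support = tuple(1.0 if f else 0.0 for f in flags)
    return ConservationProfile(
        ref_id=record.id,
        residues=record.sequence,
        support=support,
        flags=flags,
        min_fraction=1.0,
    )
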