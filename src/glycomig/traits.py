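"""Derived glycan traits: bisecting GlcNAc, fucosylation, sialylation,
galactosylation aggregates, and the Gal-ratio.

The term lists implement the published formulas verbatim.  Some lists are
arguably incomplete (``bi_n`` omits G1NFS/G2NFS; ``sial`` omits
G2S2/G1NFS/G2NFS); an ``extended=True`` mode adds those terms but is off by
default so the verbatim formulas remain the reference behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .quantify import GlycoProfile, Key

__all__ = ["TraitProfile", "compute_traits", "TRAIT_TERMS"]

TRAIT_TERMS: dict[str, tuple[str, ...]] = {
    "bi_n": ("G0N", "G0NF", "G1N", "G1NF", "G2N", "G2NF"),
    "fuc_total": (
        "G0F", "G0NF", "G0-NF", "G1F", "G1FS", "G1NF", "G1-NF", "G2F", "G2FS", "G2NF",
    ),
    "fuc_neutral": ("G0F", "G0NF", "G0-NF", "G1F", "G1NF", "G1-NF", "G2F", "G2NF"),
    "fuc_sialo": ("G1FS", "G2FS"),
    "sial": ("G1S", "G1FS", "G2FS", "G2S"),
    "g0": ("G0", "G0F", "G0N", "G0NF", "G0-NF"),
    "g1": ("G1", "G1F", "G1FS", "G1-N", "G1N", "G1NF", "G1-NF", "G1NFS", "G1S"),
    "g2": ("G2", "G2F", "G2FS", "G2N", "G2NF", "G2NFS", "G2S", "G2S2"),
}

_EXTENDED_EXTRA: dict[str, tuple[str, ...]] = {
    "bi_n": ("G1NFS", "G2NFS"),
    "fuc_total": ("G1NFS", "G2NFS"),
    "fuc_sialo": ("G1NFS", "G2NFS"),
    "sial": ("G2S2", "G1NFS", "G2NFS"),
}

_SCOPES = {"IgG1": ("IgG1",), "IgG2": ("IgG2",), "total": ("IgG1", "IgG2")}


@dataclass
class TraitProfile:
    """Derived trait fractions for one sample at one subclass scope."""

    sample_id: str
    scope: str
    bi_n: float
    fuc_total: float
    fuc_neutral: float
    fuc_sialo: float
    sial: float
    g0: float
    g1: float
    g2: float
    gal_ratio: float  # NaN when g1 + 2*g2 == 0

    @property
    def gal_ratio_defined(self) -> bool:
        return not math.isnan(self.gal_ratio)


def compute_traits(
    profile: GlycoProfile, scope: str = "total", extended: bool = False
) -> TraitProfile:
    """Derived traits over the IgG1/IgG2 abundances of one sample.

    ``scope`` selects IgG1-only, IgG2-only, or combined ("total")
    abundances, renormalized to sum 1.  IgG3/4 is always excluded (its
    isomeric signals would contaminate the traits).
    """
    if scope not in _SCOPES:
        raise ValueError(f"scope must be one of {sorted(_SCOPES)}, got {scope!r}")
    subs = _SCOPES[scope]
    selected: dict[Key, float] = {
        k: v for k, v in profile.abundances.items() if k[0] in subs
    }
    total = sum(selected.values())
    if total <= 0:
        raise ValueError(f"no abundance in scope {scope!r} for {profile.sample_id!r}")
    by_form: dict[str, float] = {}
    for (_, form), v in selected.items():
        by_form[form] = by_form.get(form, 0.0) + v / total

    def s(trait: str) -> float:
        terms = TRAIT_TERMS[trait]
        if extended and trait in _EXTENDED_EXTRA:
            terms = terms + _EXTENDED_EXTRA[trait]
        return sum(by_form.get(t, 0.0) for t in terms)

    g0, g1, g2 = s("g0"), s("g1"), s("g2")
    denom = g1 + 2.0 * g2
    gal_ratio = g0 / denom if denom > 0 else float("nan")
    return TraitProfile(
        sample_id=profile.sample_id,
        scope=scope,
        bi_n=s("bi_n"),
        fuc_total=s("fuc_total"),
        fuc_neutral=s("fuc_neutral"),
        fuc_sialo=s("fuc_sialo"),
        sial=s("sial"),
        g0=g0,
        g1=g1,
        g2=g2,
        gal_ratio=gal_ratio,
    )
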