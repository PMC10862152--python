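"""Canonical lower-leg muscle groups and age-band conventions.

Ten muscle groups are analysed (the plantaris is not among them; small
muscles are pooled into composite groups such as EEP = extensor digitorum
longus / extensor hallucis longus / peroneus tertius and PBL = peroneus
brevis + longus). Two derived aggregates are used in summaries only:
TSURAE (triceps surae = LG + MG + SOL) and TOTAL (all ten groups).

Age bands are half-open ``[lo, hi)``: the lower endpoint is included, the
upper excluded.
"""

from __future__ import annotations

#: Canonical column/analysis order of the 10 muscle groups.
MUSCLES: tuple[str, ...] = (
    "LG",   # lateral gastrocnemius
    "MG",   # medial gastrocnemius
    "SOL",  # soleus
    "TA",   # tibialis anterior
    "TP",   # tibialis posterior
    "EEP",  # ext. digitorum longus / ext. hallucis longus / peroneus tertius
    "PBL",  # peroneus brevis + longus
    "POP",  # popliteus
    "FDL",  # flexor digitorum longus
    "FHL",  # flexor hallucis longus
)

#: Components of the triceps surae aggregate.
TSURAE_MUSCLES: tuple[str, ...] = ("LG", "MG", "SOL")

#: Default cohort age bands (years), half-open [lo, hi): one infant band
#: (under ~3.6 months) and four childhood bands spanning 5-15 years.
AGE_BANDS: tuple[tuple[float, float], ...] = (
    (0.0, 0.3),
    (5.0, 7.5),
    (7.5, 10.0),
    (10.0, 12.5),
    (12.5, 15.0),
)

SEXES: tuple[str, ...] = ("boy", "girl")


def band_label(lo: float, hi: float) -> str:
    """Human-readable label for a half-open age band."""
    return f"[{lo:g},{hi:g})"


def find_band(age: float, bands=AGE_BANDS) -> tuple[float, float] | None:
    """Return the band containing ``age``, or None if it falls in a gap."""
    for lo, hi in bands:
        if lo <= age < hi:
            return (lo, hi)
    return None


def validate_bands(bands) -> None:
    """Check bands are well-formed (lo < hi) and pairwise disjoint."""
    bands = sorted(bands)
    for lo, hi in bands:
        if not lo < hi:
            raise ValueError(f"degenerate age band [{lo}, {hi})")
    for (_, hi_prev), (lo_next, _) in zip(bands, bands[1:]):
        if lo_next < hi_prev:
            raise ValueError("age bands overlap")
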