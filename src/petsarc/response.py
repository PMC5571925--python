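"""Metabolic (PERCIST-style) and histologic response classification.

Metabolic response compares body-weight SUVpeak between baseline and
post-chemotherapy studies:

* PMD — progressive metabolic disease: a new lesion, or an increase of at
  least 30% and at least 0.8 SUV units;
* CMR — complete metabolic response: post SUVpeak at or below the background
  reference;
* PMR — partial metabolic response: a decrease of at least 30% and at least
  0.8 SUV units;
* SMD — stable metabolic disease otherwise.

Precedence is PMD > CMR > PMR > SMD, so the four categories are exhaustive
and mutually exclusive.

Histologic response dichotomizes the Salzer-Kuntschik regression grade:
grades I-III (<10% viable tumor cells) are responders, IV-VI non-responders.
"""

from __future__ import annotations

PERCIST_RELATIVE = 0.30  # fractional SUVpeak change threshold
PERCIST_ABSOLUTE = 0.8  # absolute SUVpeak change threshold

METABOLIC_CATEGORIES = ("CMR", "PMR", "SMD", "PMD")


def percist_classify(
    suvpeak_pre: float,
    suvpeak_post: float,
    background_ref: float,
    new_lesion: bool = False,
) -> str:
    """One of CMR / PMR / SMD / PMD."""
    if suvpeak_pre <= 0:
        raise ValueError("baseline SUVpeak must be > 0")
    change = suvpeak_post - suvpeak_pre
    if new_lesion or (change >= PERCIST_RELATIVE * suvpeak_pre and change >= PERCIST_ABSOLUTE):
        return "PMD"
    if suvpeak_post <= background_ref:
        return "CMR"
    if -change >= PERCIST_RELATIVE * suvpeak_pre and -change >= PERCIST_ABSOLUTE:
        return "PMR"
    return "SMD"


def histologic_responder(grade: int) -> str:
    """Salzer-Kuntschik grade (1..6) -> 'responder' or 'non_responder'."""
    if not isinstance(grade, (int,)) or isinstance(grade, bool):
        raise ValueError("grade must be an integer in 1..6")
    if not 1 <= grade <= 6:
        raise ValueError(f"Salzer-Kuntschik grade {grade} out of range 1..6")
    return "responder" if grade <= 3 else "non_responder"
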