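"""Canonical gait-feature name registry.

Twenty base features are computed per step from tri-axial pelvis
acceleration.  Each base feature X is then aggregated across the steps of a
trial three ways — average ``aX``, symmetry ``sX`` (left vs right) and
variability ``vX`` — giving the 60 trial-level features used throughout the
package.  Axis prefixes: L = lateral (mediolateral), V = vertical,
A = anterior-posterior.
"""

from __future__ import annotations

# Per-step base features, in canonical column order.
BASE_FEATURES: tuple[str, ...] = (
    "M",     # mean resultant magnitude over the whole step
    "M10",   # mean resultant magnitude over the initial 10% of the step
    "LM",    # mean |lateral| over the whole step
    "VM",    # mean |vertical| over the whole step
    "AM",    # mean |anterior-posterior| over the whole step
    "MD",    # mean resultant magnitude during double stance
    "LMD",   # mean |lateral| during double stance
    "VMD",   # mean |vertical| during double stance
    "AMD",   # mean |anterior-posterior| during double stance
    "M30",   # mean resultant magnitude during mid-stance
    "LM30",  # mean |lateral| during mid-stance
    "VM30",  # mean |vertical| during mid-stance
    "AM30",  # mean |anterior-posterior| during mid-stance
    "LHM",   # lateral acceleration at the heel-strike sample
    "LHS",   # SD of lateral acceleration over the initial 10% of the step
    "VHM",   # vertical acceleration at the heel-strike sample
    "VHS",   # SD of vertical acceleration over the initial 10% of the step
    "AHM",   # anterior-posterior acceleration at the heel-strike sample
    "AHS",   # SD of anterior-posterior acceleration over the initial 10%
    "ST",    # step time in seconds
)

AGGREGATE_PREFIXES: tuple[str, ...] = ("a", "s", "v")

# The 60 trial-level feature names, prefix-major: all averages, then all
# symmetry indices, then all variabilities, each in BASE_FEATURES order.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prefix}{base}" for prefix in AGGREGATE_PREFIXES for base in BASE_FEATURES
)

OUTCOME_NAMES: tuple[str, ...] = ("peak_com_excursion", "mos_variability")

METADATA_COLUMNS: tuple[str, ...] = ("subject", "condition")


def validate_feature_names(names) -> None:
    """Raise ``ValueError`` naming any entry not in the 60-feature registry."""
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(
            f"unknown feature name(s) {unknown!r}; valid names are the 60 "
            "entries of rollgait.registry.FEATURE_NAMES"
        )
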