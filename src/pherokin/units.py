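"""Unit conversions for enzyme activity.

The canonical internal velocity unit is µM·s⁻¹.  Batch assays report activity in
picokatal (pKat = pmol·s⁻¹); converting between the two requires a reference
liquid volume, since pmol·s⁻¹ / µL = µmol·L⁻¹·s⁻¹ = µM·s⁻¹.
"""

from .errors import DomainError


def pkat_to_um_per_s(value_pkat: float, reference_volume_ul: float) -> float:
    """Convert an activity in pKat to µM·s⁻¹ given the reference volume in µL."""
    _check_volume(reference_volume_ul)
    return value_pkat / reference_volume_ul


def um_per_s_to_pkat(value_um_s: float, reference_volume_ul: float) -> float:
    """Convert a volumetric rate in µM·s⁻¹ to pKat given the reference volume in µL."""
    _check_volume(reference_volume_ul)
    return value_um_s * reference_volume_ul


def _check_volume(volume_ul: float) -> None:
    if not volume_ul > 0:
        raise DomainError(f"reference_volume_ul must be positive, got {volume_ul}")
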