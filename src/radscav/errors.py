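"""Exception and warning types shared across the package."""

from __future__ import annotations


class RadscavError(Exception):
    """Base class for package errors."""


class SchemaError(RadscavError):
    """A species table is missing a mandatory column or unit declaration."""


class ParseError(RadscavError):
    """A field could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DuplicateRecordError(RadscavError):
    """Two records share (compound_id, form, site, phase)."""


class MissingSpeciesError(RadscavError):
    """A thermochemical cycle needs a species form that is not in the set."""


class InconsistentTargetsError(RadscavError):
    """Thermochemical targets violate the cycle identity under the given references."""


class InfeasibleTargetError(RadscavError):
    """Local-descriptor targets would require negative atomic populations."""


class ConfigError(RadscavError):
    """A required configuration value (reference enthalpy, nucleophilicity
    reference, ...) was not supplied."""


class InvalidRecordError(RadscavError):
    """A species record violates a structural invariant (e.g. e_lumo < e_homo)."""


class NormalizationWarning(UserWarning):
    """A descriptor vector deviates from its expected normalization."""


class ElectronCountWarning(UserWarning):
    """Population vectors do not differ by the expected electron count."""
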