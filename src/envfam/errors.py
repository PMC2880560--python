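"""Exception hierarchy for the envfam pipeline."""


class EnvfamError(Exception):
    """Base class for all envfam errors."""


class ConfigurationError(EnvfamError):
    """An invalid configuration value; the message names the offending field."""


class FastaFormatError(EnvfamError):
    """Malformed FASTA input (including duplicate record ids)."""


class LabelError(EnvfamError):
    """A genome id without a related/unrelated set label."""


class IntervalBoundsError(EnvfamError):
    """A masking interval that does not fit its sequence."""


class IntegrityError(EnvfamError):
    """Truth-manifest inconsistency (e.g. an orphan member id)."""


class InvalidResidueError(EnvfamError):
    """A sequence containing characters outside the amino-acid alphabet."""


class CalibrationError(EnvfamError):
    """Degenerate Gumbel fit during profile-score calibration."""


class UncalibratedModelError(EnvfamError):
    """A profile scan requested before significance calibration."""


class FamilyCollapseError(EnvfamError):
    """A profile model that shrank below the minimum usable length."""
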