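"""Exception hierarchy for the MR mediation pipeline."""


class MrMediateError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrMediateError):
    """A config file or column map is malformed or incomplete."""


class DataError(MrMediateError):
    """Input data are unusable (e.g. zero valid rows after validation)."""


class NoInstrumentsError(MrMediateError):
    """No SNP survives the significance threshold for a trait."""

    def __init__(self, trait_name: str, p_threshold: float):
        self.trait_name = trait_name
        self.p_threshold = p_threshold
        super().__init__(
            f"no instruments for trait {trait_name!r} at p < {p_threshold:g}"
        )


class InsufficientInstrumentsError(MrMediateError):
    """An estimator requires more instruments than are available."""


class UndefinedRatioError(MrMediateError):
    """Wald ratio with a zero exposure effect."""


class CollinearityError(MrMediateError):
    """MVMR exposure-effect matrix is rank deficient."""


class IdentifiabilityError(MrMediateError):
    """Fewer instruments than exposures plus one in MVMR."""


class OrientationError(MrMediateError):
    """PERM called with a non-harmful total effect (OR_total <= 1)."""


class DegenerateSetError(MrMediateError):
    """Every instrument was flagged as an outlier; nothing left to correct on."""


class NoEvaluableRegionError(MrMediateError):
    """Every colocalization region was skipped (no shared SNPs)."""
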