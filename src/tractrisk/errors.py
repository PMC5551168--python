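"""Exception types shared across the pipeline."""


class TractRiskError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TractRiskError):
    """Invalid parameters, profiles, schemas, or chain ordering."""


class ChainOrderError(ConfigurationError):
    """A model spec uses a same- or later-stage outcome as a predictor."""


class SeparationError(TractRiskError):
    """Logistic response is degenerate or perfectly separated."""


class ConvergenceError(TractRiskError):
    """Iterative fit failed to converge within its iteration budget."""


class RankDeficiencyError(TractRiskError):
    """Design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"rank-deficient design; collinear columns: {self.columns}")
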