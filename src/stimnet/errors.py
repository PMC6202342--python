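"""Exception types shared across the package."""


class StimnetError(Exception):
    """Base class for stimnet-specific failures."""


class TooFewElectrodesError(StimnetError):
    """Fewer than the minimum number of analyzable electrodes remain.

    Mirrors the discard rule used for clinical subjects: a stimulation
    session with fewer than 10 surviving electrodes cannot support the
    distance-controlled regression and is dropped as a hard error.
    """


class RankDeficientDesignError(StimnetError):
    """The regression design matrix is rank deficient (collinear predictors)."""
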