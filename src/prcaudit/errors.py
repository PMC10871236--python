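"""Distinct, named exceptions for input validation and undefined quantities."""


class PRCAuditError(ValueError):
    """Base class for all prcaudit errors."""


class LengthMismatchError(PRCAuditError):
    """Scores and labels have different lengths."""


class EmptyInputError(PRCAuditError):
    """No entities supplied."""


class NonBinaryLabelError(PRCAuditError):
    """A label is neither 0 nor 1."""


class NonFiniteScoreError(PRCAuditError):
    """A score is NaN or infinite."""


class NoPositivesError(PRCAuditError):
    """AUPRC undefined: no positive entities."""


class NoNegativesError(PRCAuditError):
    """AUROC undefined: no negative entities."""


class VerticalSegmentError(PRCAuditError):
    """Expectation undefined on a segment with zero true-positive gain."""


class UnknownProfileError(PRCAuditError):
    """Requested tool profile name is not in the registry."""
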