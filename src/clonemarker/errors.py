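"""Exception hierarchy.

All package errors derive from :class:`CloneMarkerError` so callers can catch
one base class. The CLI maps :class:`ConfigError` to exit code 2 and
:class:`ConsistencyError` to exit code 3.
"""


class CloneMarkerError(Exception):
    """Base class for all package errors."""


class InvalidDesignError(CloneMarkerError):
    """A cohort design violates its invariants (rates, counts, identifiers)."""


class CapacityError(InvalidDesignError):
    """More variants requested than the genome has available positions."""


class VcfParseError(CloneMarkerError):
    """A VCF file could not be parsed; the message names the offending line."""


class ReferenceMismatchError(CloneMarkerError):
    """A variant's REF allele disagrees with the supplied reference sequence."""


class MergeConflictError(CloneMarkerError):
    """Two call sets disagree on the REF allele at the same site."""


class MarkerTableError(CloneMarkerError):
    """A marker table row could not be parsed; the message names the marker."""


class ConfigurationError(CloneMarkerError):
    """An operation was invoked without the inputs it needs (e.g. a marker
    without resolvable allele sequences)."""


class ConsistencyError(CloneMarkerError):
    """Cross-file consistency violation (unknown marker, duplicate sample,
    marker clone absent from the evaluated roster)."""


class ConfigError(CloneMarkerError):
    """Invalid pipeline configuration (missing path, out-of-domain threshold)."""
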