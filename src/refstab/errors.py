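"""Exception hierarchy shared across the package."""


class RefstabError(Exception):
    """Base class for all refstab errors."""


class DataError(RefstabError):
    """Malformed, incomplete or internally inconsistent input data."""


class DesignError(RefstabError):
    """A request that is incompatible with the experimental design
    (unknown factor level, empty subset, degenerate factor)."""
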