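"""Exception hierarchy."""


class FuncmapError(Exception):
    """Base class for all funcmap errors."""


class InputError(FuncmapError, ValueError):
    """Invalid value passed to an operation."""


class LoadError(FuncmapError):
    """A bundle file references an unknown identifier or is malformed."""


class StructureError(FuncmapError):
    """A hierarchy file implies an inconsistent tree structure."""


class SelectionError(FuncmapError):
    """A node selection violates the no-ancestor-pairs rule or names unknown nodes."""


class DesignError(FuncmapError):
    """A synthetic design is internally infeasible."""
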