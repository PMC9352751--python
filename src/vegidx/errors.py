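"""Exception hierarchy for the vegidx pipeline."""


class VegidxError(Exception):
    """Base class for all vegidx errors."""


class StructuralError(VegidxError):
    """Shape, geometry, CRS, or date mismatch between grids."""


class EncodingError(VegidxError):
    """Non-finite or otherwise unencodable index value."""


class ProductFormatError(VegidxError):
    """Corrupt or non-conforming encoded product (bad bytes, bad name, bad dtype)."""


class PeriodLookupError(VegidxError):
    """A requested (year, week) grid is absent from the archive."""


class EmptyReferenceError(VegidxError):
    """The reference policy admits no years for the requested statistic."""


class EmptyResultError(VegidxError):
    """A spatial operation produced no pixels (e.g. AOI disjoint from inputs)."""
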