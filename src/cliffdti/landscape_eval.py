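"""Alias for :mod:`cliffdti.landscape` (threshold-grid evaluation)."""

from .landscape import (DEFAULT_MIN_PAIRS, DifferentialGrid, ThresholdGrid,
                        aggregate_repeats, assign_pairs_to_cells, differential,
                        grid_metric, plot_grid)

__all__ = ["DEFAULT_MIN_PAIRS", "DifferentialGrid", "ThresholdGrid",
           "aggregate_repeats", "assign_pairs_to_cells", "differential",
           "grid_metric", "plot_grid"]
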