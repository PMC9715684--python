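"""System-level timing constants shared by every layer of the pipeline."""

SYSCLK_HZ = 240e6
"""Frequency of the free-running coarse counter (Hz)."""

T_SYSCLK_NS = 1e9 / SYSCLK_HZ
"""Coarse clock period, ~4.1667 ns.  Also the bin width of the coarse TDCs."""

COUNTER_BITS = 16
COUNTER_ROLLOVER = 1 << COUNTER_BITS
"""The on-the-wire STEP field wraps at 2**16 counts (~273 us)."""

ROLLOVER_PERIOD_NS = COUNTER_ROLLOVER * T_SYSCLK_NS

FORCE_WRITE_DIVISOR = 16
FORCE_WRITE_CYCLES = COUNTER_ROLLOVER // FORCE_WRITE_DIVISOR
"""A frame is transmitted at least once per 1/16 of the rollover (~17 us)."""

FORCE_WRITE_PERIOD_NS = FORCE_WRITE_CYCLES * T_SYSCLK_NS

LSB_PS = 48.0
"""Nominal fine-TDC tap width (least significant bit) in picoseconds."""

N_CHANNELS_DEFAULT = 25
"""Photon channels in the current hardware release (5x5 array); 49-ready."""

HEADER_IDS = (123, 124, 125, 126, 127)
"""Word identifiers of the five header words, in transmission order."""

HEADER_ID_MIN = 123
N_HEADER_WORDS = 5
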