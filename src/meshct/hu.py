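"""Hounsfield-unit conventions used throughout the package.

The stored-pixel convention follows 12-bit clinical CT: unsigned 16-bit
pixels with RescaleSlope 1 and RescaleIntercept -1024, so representable
HU span [-1024, 3071].  Air is -1000 HU, water 0 HU.
"""

HU_AIR = -1000.0
HU_WATER = 0.0
HU_MIN = -1024.0
HU_MAX = 3071.0
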