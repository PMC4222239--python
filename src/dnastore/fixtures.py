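"""Deterministic test payloads.

:func:`make_fixture_image` builds, from scratch, a valid 30 x 20 pixel,
16-colour (4 bits per pixel) BMP of exactly 438 bytes — the size class
of image this codec's six-block, 720-base layout is dimensioned for.
The image content is a synthetic glyph (border ring, diagonal band and
checkered interior), chosen so the file compresses comfortably into the
codec's 480-byte payload capacity while still exercising LZMA on
non-trivial structure.
"""

from __future__ import annotations

import struct

__all__ = ["make_fixture_image", "FIXTURE_WIDTH", "FIXTURE_HEIGHT", "FIXTURE_SIZE"]

FIXTURE_WIDTH = 30
FIXTURE_HEIGHT = 20
FIXTURE_SIZE = 438  # 14 file header + 40 DIB + 64 palette + 320 pixel bytes


def _pixel(x: int, y: int) -> int:
    """4-bit palette index at (x, y): border, diagonal band, checker fill."""
    if x in (0, FIXTURE_WIDTH - 1) or y in (0, FIXTURE_HEIGHT - 1):
        return 15
    if abs((x * FIXTURE_HEIGHT) // FIXTURE_WIDTH - y) <= 1:
        return 9
    return 12 if (x // 3 + y // 3) % 2 else 3


def make_fixture_image() -> bytes:
    """A deterministic, valid 4-bpp BMP: 30 x 20 pixels, exactly 438 bytes."""
    width, height = FIXTURE_WIDTH, FIXTURE_HEIGHT
    row_bytes = ((width * 4 + 31) // 32) * 4  # rows padded to 4-byte multiples
    image_size = row_bytes * height
    palette = b"".join(struct.pack("<BBBB", i * 17, i * 17, i * 17, 0)
                       for i in range(16))
    offset = 14 + 40 + len(palette)
    file_size = offset + image_size
    header = struct.pack("<2sIHHI", b"BM", file_size, 0, 0, offset)
    dib = struct.pack("<IiiHHIIiiII", 40, width, height, 1, 4, 0,
                      image_size, 2835, 2835, 16, 0)
    rows = []
    for y in range(height - 1, -1, -1):  # BMP rows are bottom-up
        row = bytearray()
        for x in range(0, width, 2):
            hi = _pixel(x, y)
            lo = _pixel(x + 1, y) if x + 1 < width else 0
            row.append((hi << 4) | lo)
        row.extend(b"\x00" * (row_bytes - len(row)))
        rows.append(bytes(row))
    data = header + dib + palette + b"".join(rows)
    assert len(data) == FIXTURE_SIZE
    return data
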