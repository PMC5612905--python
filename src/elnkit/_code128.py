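"""Code128 (code set B) bar encoding.

Returns the module-width sequence for a payload: start B, symbol per
character, modulo-103 checksum, stop.  Widths alternate bar/space
starting with a bar; the caller renders them at any scale.
"""

from __future__ import annotations

from .errors import ValidationError

# value -> module widths (values 0-105 are 6 modules, stop is 7)
_PATTERNS = [
    "212222", "222122", "222221", "121223", "121322", "131222", "122213",
    "122312", "132212", "221213", "221312", "231212", "112232", "122132",
    "122231", "113222", "123122", "123221", "223211", "221132", "221231",
    "213212", "223112", "312131", "311222", "321122", "321221", "312212",
    "322112", "322211", "212123", "212321", "232121", "111323", "131123",
    "131321", "112313", "132113", "132311", "211313", "231113", "231311",
    "112133", "112331", "132131", "113123", "113321", "133121", "313121",
    "211331", "231131", "213113", "213311", "213131", "311123", "311321",
    "331121", "312113", "312311", "332111", "314111", "221411", "431111",
    "111224", "111422", "121124", "121421", "141122", "141221", "112214",
    "112412", "122114", "122411", "142112", "142211", "241211", "221114",
    "413111", "241112", "134111", "111242", "121142", "121241", "114212",
    "124112", "124211", "411212", "421112", "421211", "212141", "214121",
    "412121", "111143", "111341", "131141", "114113", "114311", "411113",
    "411311", "113141", "114131", "311141", "411131", "211412", "211214",
    "211232",
]
_STOP = "2331112"
_START_B = 104


def code128_values(payload: str) -> list[int]:
    """Symbol values including start, checksum and stop."""
    if not payload:
        raise ValidationError("empty barcode payload")
    values = [_START_B]
    for ch in payload:
        code = ord(ch) - 32
        if not (0 <= code <= 94):
            raise ValidationError(
                f"character {ch!r} is outside code set B")
        values.append(code)
    checksum = values[0]
    for pos, value in enumerate(values[1:], start=1):
        checksum += pos * value
    values.append(checksum % 103)
    values.append(106)  # stop
    return values


def code128_widths(payload: str) -> list[int]:
    """Alternating bar/space module widths, starting with a bar."""
    widths: list[int] = []
    for value in code128_values(payload):
        pattern = _STOP if value == 106 else _PATTERNS[value]
        widths.extend(int(w) for w in pattern)
    return widths
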