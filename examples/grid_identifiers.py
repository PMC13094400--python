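"""Generate and validate 19-character GRID donor identifiers."""

from hladx import generate_grid, validate_grid

grid = generate_grid(issuer="9990", seed=42)
text = grid.canonical_text()
print(f"generated GRID: {text} (issuer {grid.issuer}, check '{grid.check}')")
print(f"validator says: {validate_grid(text).value}")

# truncation is always caught by the fixed length
truncated = text[:-1]
print(f"truncated to 18 chars -> {validate_grid(truncated).value}")

# any single transcription error is caught by the checksum
mutated = ("1" if text[5] != "1" else "2").join([text[:5], text[6:]])
print(f"one digit changed     -> {validate_grid(mutated).value}")
# both failures are the point: donor misidentification through truncated or
# mistyped identifiers must never pass silently
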