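"""Plot the chaos-game walk of a short sequence.

Each base pulls the current point halfway toward its corner of the unit
square (C top-left, G top-right, A bottom-left, T bottom-right), starting
from the center.  The five printed points are the exact walk of "GCACT";
the SVG shows the same walk graphically.
"""

from pathlib import Path

from cgrphylo import cgr_walk, render_cgr_svg

trail = cgr_walk("GCACT")
print("CGR walk of 'GCACT' (x, y in image coordinates, start (0.5, 0.5)):")
for base, (x, y) in zip("GCACT", trail.points):
    print(f"  {base}: ({x:.6f}, {y:.6f})")

out = Path("scratch_cgr_gcact.svg")
out.write_text(render_cgr_svg(trail, point_size=3.0))
print(f"wrote {out} — one marker per nucleotide inside the labeled square")
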