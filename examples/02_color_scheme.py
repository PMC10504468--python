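"""The imaginary-center hue scheme.

Every base pair (i, j) is colored by its imaginary center c = (i+j)/2
via H(c) = (floor(c/9) + 160*c) mod 360, so a 0.5 shift of the center —
the smallest possible, e.g. from a 1-nt bulge — moves the hue by 80 deg,
cycling through nine clearly distinct base colors.  Helices whose pairs
share one center (perfectly aligned helices) share one color.
"""

from cofoldviz import helices, hue_for_center, hue_to_hex, imaginary_center, parse_dotbracket

print("center  hue      color")
for k in range(3, 12):
    c = k / 2
    h = hue_for_center(c)
    print(f"{c:<7} {h:<8g} {hue_to_hex(h)}")
print("-> consecutive centers differ by 80 degrees of hue\n")

s = "((((....))))((((....))))"
print(f"structure: {s}")
for hx in helices(parse_dotbracket(s)):
    i, j = hx.pairs[0]
    print(f"  helix {hx.pairs}  center {hx.center} nt  hue {hue_for_center(hx.center):g}")
print("-> each helix has one center, hence one color; equal centers, equal color")

print(f"\npair (25, 38): center {imaginary_center(25, 38)} nt")
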