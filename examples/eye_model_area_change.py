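"""How much more retina does the stimulus cover when the eye elongates?

Builds the baseline and IOP-elevated spheroid eye geometries, casts the
±45° Maxwellian cone from the eye's nodal point, and prints the
illuminated areas, their percent change, and the retinal luminance factor
implied by spreading the same flash energy over the larger area.
"""

from onhlab.eye import EyeGeometry, illuminated_area, retinal_luminance_scale

baseline = EyeGeometry(axial_length_mm=7.2, transverse_diameter_mm=6.41)
elevated = EyeGeometry(axial_length_mm=7.2 * 1.043, transverse_diameter_mm=6.26)

a0 = illuminated_area(baseline)
a1 = illuminated_area(elevated)
change = 100.0 * (a1 / a0 - 1.0)
lum = retinal_luminance_scale(a0, a1)

print(f"baseline illuminated area : {a0:6.2f} mm^2")
print(f"elevated illuminated area : {a1:6.2f} mm^2")
print(f"area change               : {change:+5.1f} %")
print(f"retinal luminance factor  : {lum:5.3f}")
print()
print(
    "An ~11% larger stimulated field dims the retinal luminance by ~10% —\n"
    "far too small to explain a ~4x ERG amplitude enhancement, so global\n"
    "eyeball shape change is not the driver of the supernormal responses."
)
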