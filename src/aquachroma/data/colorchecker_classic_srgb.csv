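# 24-patch classic colour-rendition chart: nominal 8-bit sRGB renderings as
# widely circulated for the post-2005 chart. Linearised (sRGB EOCF) at load.
# These are nominal published render values, not measurements of a physical
# chart; the matching reflectance spectra used by the synthetic scene are a
# documented spectral uplift of these triples (see docs/methods.md).
name,srgb_r,srgb_g,srgb_b
dark_skin,115,82,68
light_skin,194,150,130
blue_sky,98,122,157
foliage,87,108,67
blue_flower,133,128,177
bluish_green,103,189,170
orange,214,126,44
purplish_blue,80,91,166
moderate_red,193,90,99
purple,94,60,108
yellow_green,157,188,64
orange_yellow,224,163,46
blue,56,61,150
green,70,148,73
red,175,54,60
yellow,231,199,31
magenta,187,86,149
cyan,8,133,161
white_95,243,243,242
neutral_8,200,200,200
neutral_65,160,160,160
neutral_5,122,122,121
neutral_35,85,85,85
black_2,52,52,52
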