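# Approximate MNI centroids (mm) for the 14 bilateral regions of interest,
# one row per hemisphere.  Values are literature-typical Brodmann-area
# centroids, mirrored in x across hemispheres; they are packaged reference
# data for nearest-centroid channel grouping, not subject-specific anatomy.
region,hemisphere,brodmann_areas,x,y,z
angular_gyrus,R,39,48,-64,32
angular_gyrus,L,39,-48,-64,32
dlpfc_ba9,R,9,36,34,36
dlpfc_ba9,L,9,-36,34,36
dlpfc_ba46,R,46,46,38,18
dlpfc_ba46,L,46,-46,38,18
pars_triangularis,R,45,52,28,10
pars_triangularis,L,45,-52,28,10
supramarginal_gyrus,R,40,56,-44,34
supramarginal_gyrus,L,40,-56,-44,34
middle_temporal_gyrus,R,21,58,-30,-6
middle_temporal_gyrus,L,21,-58,-30,-6
superior_temporal_gyrus,R,22,58,-22,4
superior_temporal_gyrus,L,22,-58,-22,4
somatosensory,R,1;2;3,44,-26,52
somatosensory,L,1;2;3,-44,-26,52
somatosensory_association,R,7,22,-62,58
somatosensory_association,L,7,-22,-62,58
premotor_sma,R,6,28,-4,54
premotor_sma,L,6,-28,-4,54
subcentral,R,43,58,-10,18
subcentral,L,43,-58,-10,18
inferior_frontal_gyrus,R,47,42,34,-10
inferior_frontal_gyrus,L,47,-42,34,-10
v3,R,19,36,-82,18
v3,L,19,-36,-82,18
frontal_eye_fields,R,8,28,18,48
frontal_eye_fields,L,8,-28,18,48
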