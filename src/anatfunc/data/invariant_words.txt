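# words whose singular and plural forms coincide, or singulars that end in
# -s/-es and must not be clipped; one word per line.
sheep
fish
deer
moose
swine
offspring
series
species
feces
faeces
pancreas
atlas
iris
glottis
epiglottis
cutis
pubis
naris
meatus
biceps
triceps
quadriceps
forceps
scissors
semen
lens
mumps
measles
herpes
rabies
scabies
diabetes
ascites
pertussis
news
vas
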