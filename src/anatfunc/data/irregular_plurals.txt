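# irregular English plural -> singular, one tab-separated pair per line.
# Overridable: pass a replacement table to lexical.load_tables / Normalizer.
men	man
women	woman
children	child
teeth	tooth
feet	foot
geese	goose
mice	mouse
lice	louse
people	person
oxen	ox
dice	die
genera	genus
corpora	corpus
viscera	viscus
vasa	vas
crura	crus
criteria	criterion
phenomena	phenomenon
ganglia	ganglion
mitochondria	mitochondrion
bacteria	bacterium
flagella	flagellum
cilia	cilium
labia	labium
atria	atrium
septa	septum
ostia	ostium
ova	ovum
vertebrae	vertebra
larvae	larva
pupae	pupa
antennae	antenna
aortae	aorta
fossae	fossa
bursae	bursa
conjunctivae	conjunctiva
sclerae	sclera
serosae	serosa
bronchi	bronchus
alveoli	alveolus
villi	villus
glomeruli	glomerulus
nuclei	nucleus
stimuli	stimulus
fungi	fungus
thrombi	thrombus
emboli	embolus
uteri	uterus
foci	focus
bacilli	bacillus
tali	talus
canthi	canthus
foramina	foramen
lumina	lumen
cortices	cortex
vertices	vertex
apices	apex
matrices	matrix
appendices	appendix
indices	index
cervices	cervix
varices	varix
calyces	calyx
testes	testis
analyses	analysis
diagnoses	diagnosis
prognoses	prognosis
metastases	metastasis
anastomoses	anastomosis
stenoses	stenosis
epiphyses	epiphysis
diaphyses	diaphysis
metaphyses	metaphysis
apophyses	apophysis
symphyses	symphysis
hypotheses	hypothesis
axes	axis
ellipses	ellipsis
pelves	pelvis
meninges	meninx
phalanges	phalanx
larynges	larynx
pharynges	pharynx
salpinges	salpinx
diverticula	diverticulum
spectra	spectrum
strata	stratum
frenula	frenulum
data	datum
media	medium
milia	milium
knives	knife
wives	wife
lives	life
leaves	leaf
wolves	wolf
halves	half
calves	calf
shelves	shelf
loaves	loaf
scarves	scarf
hooves	hoof
thieves	thief
selves	self
elves	elf
aches	ache
headaches	headache
moustaches	moustache
lenses	lens
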