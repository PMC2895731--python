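# English plural -> singular reference pairs (tab-separated),
# compiled from standard English and anatomical morphology.
ears	ear
lobes	lobe
bones	bone
cells	cell
organs	organ
glands	gland
nerves	nerve
valves	valve
veins	vein
muscles	muscle
tendons	tendon
ligaments	ligament
joints	joint
fingers	finger
thumbs	thumb
toes	toe
limbs	limb
arms	arm
legs	leg
hands	hand
shoulders	shoulder
elbows	elbow
knees	knee
ankles	ankle
hips	hip
ribs	rib
skulls	skull
brains	brain
hearts	heart
lungs	lung
kidneys	kidney
livers	liver
spleens	spleen
stomachs	stomach
intestines	intestine
bladders	bladder
ureters	ureter
urethras	urethra
tonsils	tonsil
adenoids	adenoid
eyelids	eyelid
eyebrows	eyebrow
pupils	pupil
retinas	retina
corneas	cornea
lenses	lens
nostrils	nostril
sinuses	sinus
tongues	tongue
lips	lip
gums	gum
jaws	jaw
chins	chin
cheeks	cheek
necks	neck
throats	throat
tracheas	trachea
vessels	vessel
capillaries	capillary
arteries	artery
ovaries	ovary
bodies	body
cavities	cavity
deformities	deformity
abnormalities	abnormality
extremities	extremity
anomalies	anomaly
therapies	therapy
biopsies	biopsy
arthropathies	arthropathy
neuropathies	neuropathy
myopathies	myopathy
studies	study
families	family
phalanges	phalanx
larynges	larynx
pharynges	pharynx
meninges	meninx
testes	testis
pelves	pelvis
axes	axis
analyses	analysis
diagnoses	diagnosis
prognoses	prognosis
metastases	metastasis
stenoses	stenosis
anastomoses	anastomosis
epiphyses	epiphysis
diaphyses	diaphysis
metaphyses	metaphysis
symphyses	symphysis
hypotheses	hypothesis
cortices	cortex
vertices	vertex
apices	apex
matrices	matrix
appendices	appendix
indices	index
cervices	cervix
varices	varix
calyces	calyx
foramina	foramen
lumina	lumen
genera	genus
corpora	corpus
viscera	viscus
crura	crus
vasa	vas
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
diverticula	diverticulum
spectra	spectrum
strata	stratum
frenula	frenulum
data	datum
media	medium
milia	milium
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
knives	knife
wives	wife
lives	life
leaves	leaf
wolves	wolf
halves	half
calves	calf
shelves	shelf
loaves	loaf
hooves	hoof
thieves	thief
selves	self
elves	elf
sheep	sheep
fish	fish
deer	deer
species	species
series	series
feces	feces
pancreas	pancreas
biceps	biceps
forceps	forceps
scissors	scissors
lens	lens
masses	mass
glasses	glass
processes	process
illnesses	illness
weaknesses	weakness
abscesses	abscess
classes	class
crosses	cross
reflexes	reflex
boxes	box
taxes	tax
fixes	fix
branches	branch
patches	patch
arches	arch
pouches	pouch
rashes	rash
flushes	flush
brushes	brush
noses	nose
doses	dose
cases	case
bases	base
pulses	pulse
impulses	impulse
responses	response
viruses	virus
fetuses	fetus
statuses	status
plexuses	plexus
sizes	size
enzymes	enzyme
genes	gene
proteins	protein
tissues	tissue
membranes	membrane
follicles	follicle
ventricles	ventricle
fibers	fiber
fibrils	fibril
neurons	neuron
synapses	synapse
axons	axon
dendrites	dendrite
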