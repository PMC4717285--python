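term,definition
biopsy,"Taking a small piece of body tissue so doctors can look at it under a microscope."
biopsies,"Taking small pieces of body tissue so doctors can look at them under a microscope."
placebo,"A treatment with no medicine in it, used to compare against the real treatment."
metastatic,"Cancer that has spread from where it started to another part of the body."
investigational drug,"A medicine that is still being studied and is not yet approved for everyone."
eligibility,"The rules about who is allowed to join a study."
protocol,"The detailed plan that a study follows."
infusion,"Medicine given slowly into a vein through a small tube."
venipuncture,"Taking blood from a vein with a needle."
endoscopy,"Looking inside the body with a thin tube that has a light and camera."
catheterization,"Placing a thin soft tube into the body, for example into a blood vessel."
aspiration,"Using a needle to draw fluid or cells out of the body."
resection,"Surgery to remove part of an organ or a growth."
transplantation,"Replacing damaged cells or organs with healthy ones from a donor."
debridement,"Cleaning a wound by removing damaged tissue."
thoracentesis,"Using a needle to remove fluid from around the lungs."
randomized,"Assigned to a study group by chance, like flipping a coin."
informed consent,"The conversation and paperwork that explain a study before you agree to join."
oncology,"The area of medicine that deals with cancer."
remission,"A time when cancer signs and symptoms are reduced or gone."
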