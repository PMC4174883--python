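<Lems>
    <!-- Conductance-based synapse with a double-exponential waveform, a
         voltage/concentration-dependent block mechanism (magnesium-block
         style) and a two-variable short-term plasticity mechanism
         (depression + facilitation).  Spikes arriving at the synapse are
         relayed to the plasticity child through a parent-to-child event
         connection declared in the child's Structure. -->

    <Include file="defs.xml"/>
    <Include file="basetypes.xml"/>

    <ComponentType name="baseBlockMechanism">
        <Exposure name="blockFactor" dimension="none"/>
    </ComponentType>

    <ComponentType name="voltageConcDepBlockMechanism" extends="baseBlockMechanism">
        <Parameter name="blockConcentration" dimension="concentration"/>
        <Parameter name="scalingConc" dimension="concentration"/>
        <Parameter name="scalingVolt" dimension="voltage"/>
        <Requirement name="v" dimension="voltage"/>
        <Dynamics>
            <DerivedVariable name="blockFactor" dimension="none" exposure="blockFactor"
                value="1 / (1 + (blockConcentration / scalingConc) * exp(0 - v / scalingVolt))"/>
        </Dynamics>
    </ComponentType>

    <ComponentType name="basePlasticityMechanism">
        <Exposure name="plasticityFactor" dimension="none"/>
        <EventPort name="in" direction="in"/>
    </ComponentType>

    <!-- Two-variable short-term plasticity: R is the recovered resource
         fraction, U the utilization.  Between spikes R recovers toward 1
         with tauRec and U decays toward its baseline with tauFac; on each
         spike R is depleted by U*R and U facilitates toward 1. -->
    <ComponentType name="tsodyksMarkramDepFacMechanism" extends="basePlasticityMechanism">
        <Parameter name="initReleaseProb" dimension="none"/>
        <Parameter name="tauRec" dimension="time"/>
        <Parameter name="tauFac" dimension="time"/>
        <Dynamics>
            <StateVariable name="U" dimension="none"/>
            <StateVariable name="R" dimension="none"/>
            <DerivedVariable name="plasticityFactor" dimension="none"
                             exposure="plasticityFactor" value="U * R"/>
            <TimeDerivative variable="U" value="(initReleaseProb - U) / tauFac"/>
            <TimeDerivative variable="R" value="(1 - R) / tauRec"/>
            <OnStart>
                <StateAssignment variable="U" value="initReleaseProb"/>
                <StateAssignment variable="R" value="1"/>
            </OnStart>
            <OnEvent port="in">
                <StateAssignment variable="R" value="R - U * R"/>
                <StateAssignment variable="U" value="U + initReleaseProb * (1 - U)"/>
            </OnEvent>
        </Dynamics>
        <Structure>
            <EventConnection from="parent" to="this" sourcePort="in" targetPort="in"/>
        </Structure>
    </ComponentType>

    <ComponentType name="blockingPlasticSynapse" extends="baseSynapse">
        <Parameter name="gbase" dimension="conductance"/>
        <Parameter name="erev" dimension="voltage"/>
        <Parameter name="tauRise" dimension="time"/>
        <Parameter name="tauDecay" dimension="time"/>
        <Requirement name="v" dimension="voltage"/>
        <Exposure name="g" dimension="conductance"/>
        <Child name="blockMechanism" type="baseBlockMechanism"/>
        <Child name="plasticityMechanism" type="basePlasticityMechanism"/>
        <Dynamics>
            <StateVariable name="A" dimension="none"/>
            <StateVariable name="B" dimension="none"/>
            <DerivedVariable name="blockFactor" dimension="none"
                             select="blockMechanism/blockFactor"/>
            <DerivedVariable name="plasticityFactor" dimension="none"
                             select="plasticityMechanism/plasticityFactor"/>
            <DerivedVariable name="g" dimension="conductance" exposure="g"
                             value="gbase * blockFactor * (B - A)"/>
            <DerivedVariable name="i" dimension="current" exposure="i"
                             value="g * (erev - v)"/>
            <TimeDerivative variable="A" value="(0 - A) / tauRise"/>
            <TimeDerivative variable="B" value="(0 - B) / tauDecay"/>
            <OnEvent port="in">
                <StateAssignment variable="A" value="A + weight * plasticityFactor"/>
                <StateAssignment variable="B" value="B + weight * plasticityFactor"/>
            </OnEvent>
        </Dynamics>
    </ComponentType>
</Lems>
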